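"""Sinusoid-noise stimulus generation for reverse-correlation experiments.

A noise field is a weighted sum of truncated sinusoid gratings: for every
spatial scale (cycles per image), orientation, and phase, the image is tiled
into square patches and each patch receives an independent uniform weight.
With the default 5 scales (2, 4, 8, 16, 32 cycles), 6 orientations, and 2
phases this gives 4,092 weights — the standard parameterization used for
face classification-image work.

Each stimulus pair consists of a noise field and its exact element-wise
negation superimposed on one grayscale base face, so a two-alternative
forced choice between the pair isolates the perceptual contribution of the
noise.  All generation is counter-based deterministic: field ``i`` of a set
depends only on ``(rng_seed, i)``, never on generation order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseParams",
    "NoiseField",
    "BaseFace",
    "Stimulus",
    "StimulusSet",
    "generate_noise_field",
    "invert_noise",
    "build_stimulus_set",
    "render_stimulus",
    "synthetic_base_face",
    "load_base_face",
    "save_stimulus_set",
    "load_stimulus_set",
]


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the sinusoid noise basis.

    Attributes
    ----------
    image_size:
        Pixels per side of the square stimulus grid (even, >= 32).
    n_scales, cycles_per_scale:
        Number of spatial-frequency scales and the (strictly increasing)
        cycles-per-image of each.  Each scale of ``c`` cycles is tiled into
        ``(c/2) x (c/2)`` patches of two cycles each.
    n_orientations:
        Grating orientations, evenly spaced on [0, pi).
    n_phases:
        Phases, spaced pi/2 apart starting at 0 (the default 2 gives the
        sine/cosine quadrature pair).
    weight_range:
        Closed interval for the i.i.d. uniform basis weights; must be
        symmetric about 0 so the noise ensemble has zero mean.
    rng_seed:
        Integer seed; together with a draw index it fully determines a field.
    """

    image_size: int = 512
    n_scales: int = 5
    cycles_per_scale: tuple[int, ...] = (2, 4, 8, 16, 32)
    n_orientations: int = 6
    n_phases: int = 2
    weight_range: tuple[float, float] = (-1.0, 1.0)
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cycles_per_scale", tuple(int(c) for c in self.cycles_per_scale))
        object.__setattr__(self, "weight_range", tuple(float(w) for w in self.weight_range))
        self.validate()

    def validate(self) -> None:
        if self.image_size < 32 or self.image_size % 2 != 0:
            raise ConfigurationError(
                f"image_size must be an even integer >= 32, got {self.image_size}"
            )
        if self.n_scales < 1 or len(self.cycles_per_scale) != self.n_scales:
            raise ConfigurationError(
                f"cycles_per_scale must list n_scales={self.n_scales} entries, "
                f"got {len(self.cycles_per_scale)}"
            )
        if any(c2 <= c1 for c1, c2 in zip(self.cycles_per_scale, self.cycles_per_scale[1:])):
            raise ConfigurationError(
                f"cycles_per_scale must be strictly increasing, got {self.cycles_per_scale}"
            )
        for c in self.cycles_per_scale:
            if c < 2 or c % 2 != 0:
                raise ConfigurationError(f"cycles_per_scale entries must be even and >= 2, got {c}")
            if self.image_size % (c // 2) != 0:
                raise ConfigurationError(
                    f"image_size={self.image_size} is not divisible by the "
                    f"{c // 2}-patch grid of the {c}-cycle scale"
                )
        if self.n_orientations < 1:
            raise ConfigurationError(f"n_orientations must be >= 1, got {self.n_orientations}")
        if self.n_phases < 1:
            raise ConfigurationError(f"n_phases must be >= 1, got {self.n_phases}")
        lo, hi = self.weight_range
        if not (hi > 0 and lo == -hi):
            raise ConfigurationError(
                f"weight_range must be symmetric about 0 with positive width, got {self.weight_range}"
            )

    @property
    def n_weights(self) -> int:
        """Total number of basis weights (patches x orientations x phases)."""
        patches = sum((c // 2) ** 2 for c in self.cycles_per_scale)
        return patches * self.n_orientations * self.n_phases

    def _basis_key(self) -> tuple:
        return (self.image_size, self.cycles_per_scale, self.n_orientations, self.n_phases)


@lru_cache(maxsize=8)
def _basis_layers(key: tuple) -> tuple:
    """Precompute the grating of every (scale, orientation, phase) layer.

    Returns a tuple of ``(grating, n_patch, patch_px)`` triples in the fixed
    weight-vector order: scales outer, then orientations, then phases; patch
    weights within a layer are row-major.
    """
    image_size, cycles, n_orientations, n_phases = key
    coords = np.arange(image_size, dtype=np.float64)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    layers = []
    for c in cycles:
        n_patch = c // 2
        patch_px = image_size // n_patch
        for k in range(n_orientations):
            theta = k * math.pi / n_orientations
            carrier = (xx * math.cos(theta) + yy * math.sin(theta)) * (2.0 * math.pi * c / image_size)
            for j in range(n_phases):
                grating = np.sin(carrier + j * math.pi / 2.0)
                layers.append((grating, n_patch, patch_px))
    return tuple(layers)


def expand_weights(weights: np.ndarray, params: NoiseParams) -> np.ndarray:
    """Linear expansion of a weight vector into an ``image_size**2`` field.

    The map is linear and sign-symmetric at the IEEE level, so
    ``expand(-w) == -expand(w)`` holds *exactly* — the inverse-pair and
    CI-cancellation invariants rely on this.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (params.n_weights,):
        raise ConfigurationError(
            f"expected weight vector of length {params.n_weights}, got shape {weights.shape}"
        )
    values = np.zeros((params.image_size, params.image_size))
    i = 0
    for grating, n_patch, patch_px in _basis_layers(params._basis_key()):
        k = n_patch * n_patch
        w = weights[i : i + k].reshape(n_patch, n_patch)
        values += w.repeat(patch_px, axis=0).repeat(patch_px, axis=1) * grating
        i += k
    return values


@dataclass(eq=False)
class NoiseField:
    """A zero-mean contrast pattern defined by its basis weights."""

    weights: np.ndarray
    params: NoiseParams
    field_id: str
    _values: np.ndarray | None = field(default=None, repr=False)

    @property
    def values(self) -> np.ndarray:
        """Pixel matrix; computed lazily from the weights and cached."""
        if self._values is None:
            self._values = expand_weights(self.weights, self.params)
        return self._values


def generate_noise_field(params: NoiseParams, draw_index: int) -> NoiseField:
    """Draw noise field ``draw_index`` of the stream seeded by ``params.rng_seed``.

    Counter-based: the result depends only on ``(rng_seed, draw_index)``, so
    fields may be generated in any order or in parallel.
    """
    params.validate()
    if draw_index < 0:
        raise ConfigurationError(f"draw_index must be >= 0, got {draw_index}")
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed, spawn_key=(draw_index,)))
    lo, hi = params.weight_range
    weights = rng.uniform(lo, hi, params.n_weights)
    return NoiseField(weights=weights, params=params, field_id=f"s{params.rng_seed}d{draw_index}")


def invert_noise(noise: NoiseField) -> NoiseField:
    """Exact element-wise negation; an involution (invert∘invert == identity)."""
    inv_id = noise.field_id[:-4] if noise.field_id.endswith("~inv") else noise.field_id + "~inv"
    inv = NoiseField(weights=-noise.weights, params=noise.params, field_id=inv_id)
    if noise._values is not None:
        inv._values = -noise._values
    return inv


@dataclass
class BaseFace:
    """Grayscale base image with pixels scaled to [0, 1]."""

    pixels: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise InputError(f"base face must be a square grayscale matrix, got {self.pixels.shape}")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise InputError("base face pixels must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def synthetic_base_face(image_size: int = 512, label: str = "synthetic") -> BaseFace:
    """Deterministic synthetic stand-in for a composite base face.

    A smooth face-like luminance pattern (oval head, darker eye and mouth
    regions, a nose ridge) built from Gaussian blobs.  It has the gross
    spatial statistics a noise field is superimposed on — a mid-gray figure
    on a darker ground — without any photographic content.
    """
    n = image_size
    y, x = np.mgrid[0:n, 0:n] / (n - 1.0)

    def blob(cx, cy, sx, sy):
        return np.exp(-(((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2) / 2.0)

    img = 0.25 + 0.45 * blob(0.5, 0.52, 0.20, 0.28)          # head oval
    img += 0.10 * blob(0.5, 0.30, 0.16, 0.10)                # forehead highlight
    img -= 0.18 * blob(0.36, 0.42, 0.05, 0.030)              # left eye
    img -= 0.18 * blob(0.64, 0.42, 0.05, 0.030)              # right eye
    img += 0.08 * blob(0.5, 0.55, 0.030, 0.085)              # nose ridge
    img -= 0.14 * blob(0.5, 0.72, 0.085, 0.028)              # mouth
    return BaseFace(pixels=np.clip(img, 0.0, 1.0), label=label)


def load_base_face(path: str | Path, image_size: int | None = None, label: str = "") -> BaseFace:
    """Load a grayscale PNG/TIFF base face, resampling to ``image_size`` if needed."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("L")
            if im.size[0] != im.size[1]:
                raise InputError(f"base face {path} is not square: {im.size}")
            if image_size is not None and im.size != (image_size, image_size):
                logger.info(
                    "resampling base face %s from %s to %dx%d (bicubic)",
                    path, im.size, image_size, image_size,
                )
                im = im.resize((image_size, image_size), Image.BICUBIC)
            pixels = np.asarray(im, dtype=np.float64) / 255.0
    except InputError:
        raise
    except OSError as exc:
        raise InputError(f"cannot read base face image {path}: {exc}") from exc
    return BaseFace(pixels=pixels, label=label or path.stem)


@dataclass(eq=False)
class Stimulus:
    """One member of an inverse pair: a noise field with a polarity sign."""

    stimulus_id: str
    pair_id: str
    polarity: int  # +1 or -1
    noise: NoiseField


@dataclass(eq=False)
class StimulusSet:
    """An ordered collection of inverse stimulus pairs over one base face."""

    set_id: str
    base: BaseFace
    params: NoiseParams
    pairs: list[tuple[Stimulus, Stimulus]]
    display_fraction: float = 0.4
    _display_scale: float | None = field(default=None, repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def stimuli(self) -> Iterator[Stimulus]:
        for a, b in self.pairs:
            yield a
            yield b

    def pair(self, pair_id: str) -> tuple[Stimulus, Stimulus]:
        if not hasattr(self, "_pair_index"):
            self._pair_index = {a.pair_id: (a, b) for a, b in self.pairs}
        try:
            return self._pair_index[pair_id]
        except KeyError:
            raise KeyError(f"pair_id {pair_id!r} not in stimulus set {self.set_id!r}") from None

    @property
    def pair_ids(self) -> list[str]:
        return [a.pair_id for a, _ in self.pairs]

    @property
    def display_scale(self) -> float:
        """Contrast-to-pixel factor shared by the whole set.

        Chosen once so the largest absolute noise value across the set maps
        to ``display_fraction`` of the [0, 1] dynamic range; a single shared
        constant keeps rendered pairs exact inverses about the base face.
        Computed lazily (it requires expanding every field to pixels).
        """
        if self._display_scale is None:
            peak = max(float(np.abs(a.noise.values).max()) for a, _ in self.pairs)
            if peak == 0.0:
                peak = 1.0
            self._display_scale = self.display_fraction / peak
        return self._display_scale


def build_stimulus_set(
    base: BaseFace,
    params: NoiseParams,
    n_pairs: int = 300,
    set_id: str | None = None,
    display_fraction: float = 0.4,
) -> StimulusSet:
    """Generate ``n_pairs`` inverse pairs of noise stimuli on ``base``.

    Pair ``i`` uses noise draw ``i`` for its +1 member and the exact negation
    for its -1 member; regenerating with the same ``(params, n_pairs)``
    reproduces every weight and pixel bit-identically.
    """
    if n_pairs < 1:
        raise ConfigurationError(f"n_pairs must be >= 1, got {n_pairs}")
    if display_fraction <= 0:
        raise ConfigurationError(f"display_fraction must be > 0, got {display_fraction}")
    if base.size != params.image_size:
        logger.info(
            "resampling base face %r from %d to %d px (bicubic)",
            base.label, base.size, params.image_size,
        )
        im = Image.fromarray(np.round(base.pixels * 255.0).astype(np.uint8), mode="L")
        im = im.resize((params.image_size, params.image_size), Image.BICUBIC)
        base = BaseFace(pixels=np.asarray(im, dtype=np.float64) / 255.0, label=base.label)
    if set_id is None:
        set_id = f"set{params.rng_seed}"
    pairs = []
    for i in range(n_pairs):
        fwd = generate_noise_field(params, i)
        pair_id = f"p{i:04d}"
        pairs.append(
            (
                Stimulus(f"{pair_id}_pos", pair_id, +1, fwd),
                Stimulus(f"{pair_id}_neg", pair_id, -1, invert_noise(fwd)),
            )
        )
    return StimulusSet(set_id=set_id, base=base, params=params, pairs=pairs,
                       display_fraction=display_fraction)


def render_stimulus(base: BaseFace, noise: NoiseField, display_scale: float) -> np.ndarray:
    """Superimpose a noise field on the base face as an 8-bit grayscale image.

    ``pixel = clip(base + display_scale * noise, 0, 1)`` quantized to uint8.
    """
    if display_scale <= 0:
        raise InputError(f"display_scale must be > 0, got {display_scale}")
    if base.pixels.shape != noise.values.shape:
        raise InputError(
            f"base {base.pixels.shape} and noise {noise.values.shape} shapes differ"
        )
    img = np.clip(base.pixels + display_scale * noise.values, 0.0, 1.0)
    return np.round(img * 255.0).astype(np.uint8)


def _save_png(array: np.ndarray, path: Path) -> None:
    Image.fromarray(array, mode="L").save(path, format="PNG")


def save_stimulus_set(sset: StimulusSet, out_dir: str | Path, write_images: bool = True) -> Path:
    """Write stimulus PNGs, the manifest CSV, and a parameter sidecar.

    The manifest (``{set_id}_manifest.csv``) is the source of truth for a
    session: set_id, pair_id, stimulus_id, polarity, seed, display_scale and
    image path of every stimulus.  ``{set_id}_params.json`` records the full
    noise parameterization so the set can be regenerated bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scale = sset.display_scale
    rows = []
    for stim in sset.stimuli():
        suffix = "pos" if stim.polarity > 0 else "neg"
        img_name = f"{sset.set_id}_{stim.pair_id}_{suffix}.png"
        if write_images:
            _save_png(render_stimulus(sset.base, stim.noise, scale), out_dir / img_name)
        rows.append(
            {
                "set_id": sset.set_id,
                "pair_id": stim.pair_id,
                "stimulus_id": stim.stimulus_id,
                "polarity": stim.polarity,
                "seed": sset.params.rng_seed,
                "display_scale": scale,
                "image_path": img_name,
            }
        )
    manifest_path = out_dir / f"{sset.set_id}_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False, float_format="%.12g")
    params_path = out_dir / f"{sset.set_id}_params.json"
    meta = {
        "set_id": sset.set_id,
        "n_pairs": sset.n_pairs,
        "display_fraction": sset.display_fraction,
        "params": {
            "image_size": sset.params.image_size,
            "n_scales": sset.params.n_scales,
            "cycles_per_scale": list(sset.params.cycles_per_scale),
            "n_orientations": sset.params.n_orientations,
            "n_phases": sset.params.n_phases,
            "weight_range": list(sset.params.weight_range),
            "rng_seed": sset.params.rng_seed,
        },
        "base_label": sset.base.label,
    }
    params_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    _save_png(np.round(sset.base.pixels * 255.0).astype(np.uint8), out_dir / f"{sset.set_id}_base.png")
    return manifest_path


def load_stimulus_set(manifest_path: str | Path) -> StimulusSet:
    """Reconstruct a StimulusSet from a manifest written by :func:`save_stimulus_set`.

    Noise fields are regenerated from the recorded seed and parameters (the
    manifest, not the PNGs, is authoritative); stimulus ids are checked
    against the manifest rows.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"set_id", "pair_id", "stimulus_id", "polarity", "seed", "display_scale"}
    if not required.issubset(manifest.columns):
        raise InputError(f"manifest {manifest_path} missing columns {sorted(required - set(manifest.columns))}")
    set_id = str(manifest["set_id"].iloc[0])
    params_path = manifest_path.with_name(f"{set_id}_params.json")
    if not params_path.exists():
        raise InputError(f"parameter sidecar {params_path} not found next to manifest")
    meta = json.loads(params_path.read_text())
    params = NoiseParams(**{**meta["params"], "cycles_per_scale": tuple(meta["params"]["cycles_per_scale"]),
                            "weight_range": tuple(meta["params"]["weight_range"])})
    base_path = manifest_path.with_name(f"{set_id}_base.png")
    if base_path.exists():
        base = load_base_face(base_path, image_size=params.image_size, label=meta.get("base_label", ""))
    else:
        base = synthetic_base_face(params.image_size, label=meta.get("base_label", "synthetic"))
    sset = build_stimulus_set(base, params, n_pairs=int(meta["n_pairs"]), set_id=set_id,
                              display_fraction=float(meta.get("display_fraction", 0.4)))
    manifest_ids = set(manifest["stimulus_id"].astype(str))
    built_ids = {s.stimulus_id for s in sset.stimuli()}
    if manifest_ids != built_ids:
        raise InputError(
            f"manifest stimulus ids do not match regenerated set "
            f"({len(manifest_ids ^ built_ids)} mismatching ids)"
        )
    return sset
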