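"""Synthetic 4D BOLD phantoms with planted network structure.

This module builds everything the downstream analysis needs without any
acquired data: a labeled phantom "brain" whose structures are grouped into
seven functional networks (VIS, EX, SM, CERE, DMN, SAL, BAS), resting-state
and block-design stimulus paradigms, and per-subject 4D BOLD runs in which
every structure of a network shares one latent time course.  An injury is
planted multiplicatively: selected structures have their BOLD amplitude
attenuated (damage) while others are elevated (compensation), which is what
the decomposition + permutation pipeline is meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from nilearn.glm.first_level import spm_hrf
from scipy import signal as sps

__all__ = [
    "AtlasSet",
    "StimulusDesign",
    "BoldSeries",
    "EffectSpec",
    "PlacementError",
    "STRUCTURE_INVENTORY",
    "NETWORK_NAMES",
    "make_phantom_atlas",
    "make_design",
    "simulate_subject",
    "band_limited_noise",
]

#: (structure_name, network) inventory.  EX has seven cortical structures,
#: VIS and SM three each; CERE, DMN, SAL and BAS are represented by a single
#: aggregate structure each (their member anatomies are not resolved).
STRUCTURE_INVENTORY: tuple[tuple[str, str], ...] = (
    ("VIS1: primary visual cortex", "VIS"),
    ("VIS2: secondary visual cortex", "VIS"),
    ("VIS3: associative visual cortex", "VIS"),
    ("EX1: primary somatosensory cortex", "EX"),
    ("EX2: dorsolateral prefrontal cortex", "EX"),
    ("EX3: anterior prefrontal cortex", "EX"),
    ("EX4: orbitofrontal cortex", "EX"),
    ("EX5: insular cortex", "EX"),
    ("EX6: ventral anterior cingulate cortex", "EX"),
    ("EX7: dorsal anterior cingulate cortex", "EX"),
    ("SM1: primary motor cortex", "SM"),
    ("SM2: somatosensory associative cortex", "SM"),
    ("SM3: premotor cortex", "SM"),
    ("CERE: cerebellum", "CERE"),
    ("DMN: default mode network (aggregate)", "DMN"),
    ("SAL: salience network (aggregate)", "SAL"),
    ("BAS: basal ganglia (aggregate)", "BAS"),
)

NETWORK_NAMES = ("VIS", "EX", "SM", "CERE", "DMN", "SAL", "BAS")


class PlacementError(RuntimeError):
    """Raised when a structure cannot be placed inside the brain mask."""


@dataclass
class AtlasSet:
    """3D integer label volume plus the structure -> network registry.

    ``label_volume`` uses 0 for background/non-brain and positive integers
    for structures.  ``structures`` maps each label to its name and network.
    """

    label_volume: np.ndarray
    brain_mask: np.ndarray
    structures: list[tuple[int, str, str]]  # (label, structure_name, network)

    @property
    def networks(self) -> dict[str, np.ndarray]:
        """network name -> binary mask (exact union of member structures)."""
        out: dict[str, np.ndarray] = {}
        for label, _name, net in self.structures:
            m = self.label_volume == label
            out[net] = out.get(net, np.zeros_like(m)) | m
        return out

    def structure_mask(self, name: str) -> np.ndarray:
        for label, sname, _net in self.structures:
            if sname == name or sname.split(":")[0] == name:
                return self.label_volume == label
        raise KeyError(f"unknown structure {name!r}")

    def network_structures(self, network: str) -> list[tuple[int, str]]:
        return [(lab, nm) for lab, nm, net in self.structures if net == network]

    def validate(self) -> None:
        labels = self.label_volume[self.label_volume > 0]
        if not self.brain_mask[self.label_volume > 0].all():
            raise ValueError("labeled voxel outside brain mask")
        known = {lab for lab, _, _ in self.structures}
        if not set(np.unique(labels)) <= known:
            raise ValueError("label volume contains unregistered labels")


@dataclass
class StimulusDesign:
    """Stimulus paradigm sampled at the repetition time.

    ``regressor`` is the expected BOLD response per volume: all-zero for
    rest, and a peak-normalized boxcar (x) HRF convolution for block designs.
    ``boxcar`` keeps the pre-convolution 0/1 stimulus indicator.
    """

    tr: float
    n_volumes: int
    paradigm: str  # "rest" | "block"
    regressor: np.ndarray
    boxcar: np.ndarray

    def __post_init__(self) -> None:
        if len(self.regressor) != self.n_volumes:
            raise ValueError("regressor length must equal n_volumes")


@dataclass
class BoldSeries:
    """One subject's 4D BOLD run (X x Y x Z x T)."""

    data: np.ndarray
    tr: float
    brain_mask: np.ndarray
    subject_id: str
    group: str  # "control" | "injured"

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(
                f"BoldSeries data must be 4D, got {self.data.ndim}D"
            )
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain_mask dimensions do not match data")
        if self.data.shape[3] < 1:
            raise ValueError("series must contain at least one volume")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])


@dataclass
class EffectSpec:
    """Planted injury effect: multiplicative amplitude factors per structure.

    ``attenuated`` structures (factor in [0, 1)) model damaged areas;
    ``elevated`` ones (factor > 1) model compensation.  Factors apply only to
    subjects in the injured group.
    """

    attenuated: dict[str, float] = field(default_factory=dict)
    elevated: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    ar1: float = 0.3
    amplitude_jitter: float = 0.1

    def __post_init__(self) -> None:
        overlap = set(self.attenuated) & set(self.elevated)
        if overlap:
            raise ValueError(f"structures both attenuated and elevated: {overlap}")
        for name, f in self.attenuated.items():
            if not 0 <= f < 1:
                raise ValueError(f"attenuation factor for {name} must be in [0,1)")
        for name, f in self.elevated.items():
            if f <= 1:
                raise ValueError(f"elevation factor for {name} must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0,1)")

    def factor(self, structure_name: str) -> float:
        key = structure_name.split(":")[0]
        for table in (self.attenuated, self.elevated):
            for k, v in table.items():
                if k == structure_name or k == key:
                    return float(v)
        return 1.0


def make_phantom_atlas(
    grid_dims: tuple[int, int, int] = (24, 24, 16),
    seed: int = 0,
    radius_range: tuple[float, float] = (1.8, 2.8),
    max_tries: int = 2000,
) -> AtlasSet:
    """Build the phantom atlas: ellipsoidal brain, 17 blob structures.

    Structures are ellipsoidal blobs placed at random (seeded) positions,
    pairwise disjoint and fully inside the brain mask.  Raises
    :class:`PlacementError` naming the first structure that cannot be placed.
    """
    dims = tuple(int(d) for d in grid_dims)
    if len(dims) != 3 or any(d < 16 for d in dims):
        raise ValueError("each grid dimension must be >= 16")
    rng = np.random.default_rng(seed)

    centers = [(d - 1) / 2.0 for d in dims]
    semi = [0.46 * d for d in dims]
    xx, yy, zz = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    brain = (
        ((xx - centers[0]) / semi[0]) ** 2
        + ((yy - centers[1]) / semi[1]) ** 2
        + ((zz - centers[2]) / semi[2]) ** 2
    ) <= 1.0

    labels = np.zeros(dims, dtype=np.int16)
    structures: list[tuple[int, str, str]] = []
    lo, hi = radius_range
    # sample blob centers from the brain interior so most tries fit
    interior = (
        ((xx - centers[0]) / (semi[0] - hi)) ** 2
        + ((yy - centers[1]) / (semi[1] - hi)) ** 2
        + ((zz - centers[2]) / (semi[2] - hi)) ** 2
    ) <= 1.0
    brain_idx = np.argwhere(interior if interior.any() else brain)
    for i, (name, net) in enumerate(STRUCTURE_INVENTORY, start=1):
        placed = False
        for _ in range(max_tries):
            cx, cy, cz = brain_idx[rng.integers(len(brain_idx))]
            rad = rng.uniform(lo, hi, size=3)
            blob = (
                ((xx - cx) / rad[0]) ** 2
                + ((yy - cy) / rad[1]) ** 2
                + ((zz - cz) / rad[2]) ** 2
            ) <= 1.0
            if blob.sum() < 8:
                continue
            if not brain[blob].all():
                continue
            if (labels[blob] != 0).any():
                continue
            labels[blob] = i
            structures.append((i, name, net))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place structure {name!r} on grid {dims} "
                f"after {max_tries} tries"
            )
    atlas = AtlasSet(label_volume=labels, brain_mask=brain, structures=structures)
    atlas.validate()
    return atlas


def _canonical_hrf(tr: float) -> np.ndarray:
    """Canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6)
    sampled at the repetition time."""
    return spm_hrf(tr, oversampling=1)


def make_design(
    paradigm: str,
    tr: float,
    n_volumes: int | None = None,
    dead_time: float = 15.0,
    block_on: float = 30.0,
    block_off: float = 30.0,
    n_cycles: int = 6,
) -> StimulusDesign:
    """Build a rest or block stimulus design sampled at ``tr``.

    For ``block``, the regressor is the 0/1 boxcar (dead time, then
    ``n_cycles`` of ON/OFF) convolved with the canonical HRF, truncated to
    the run length and peak-normalized to 1.  For ``rest`` the regressor is
    all-zero.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if paradigm == "rest":
        if n_volumes is None:
            raise ValueError("rest design requires n_volumes")
        z = np.zeros(int(n_volumes))
        return StimulusDesign(tr=tr, n_volumes=int(n_volumes), paradigm="rest",
                              regressor=z, boxcar=z.copy())
    if paradigm != "block":
        raise ValueError(f"unknown paradigm {paradigm!r}")

    for nm, dur in (("dead_time", dead_time), ("block_on", block_on),
                    ("block_off", block_off)):
        if abs(dur / tr - round(dur / tr)) > 1e-9:
            raise ValueError(f"{nm} must be an integer multiple of tr")
    total = dead_time + n_cycles * (block_on + block_off)
    n_total = int(round(total / tr))
    if n_volumes is None:
        n_volumes = n_total
    elif n_volumes * tr != total:
        raise ValueError(
            f"inconsistent design: dead_time + cycles x (on+off) = {total} s "
            f"but n_volumes x tr = {n_volumes * tr} s"
        )
    box = np.zeros(n_total)
    pos = int(round(dead_time / tr))
    on_v, off_v = int(round(block_on / tr)), int(round(block_off / tr))
    for _ in range(n_cycles):
        box[pos:pos + on_v] = 1.0
        pos += on_v + off_v
    hrf = _canonical_hrf(tr)
    reg = np.convolve(box, hrf)[:n_total]
    peak = np.abs(reg).max()
    if peak > 0:
        reg = reg / peak
    return StimulusDesign(tr=tr, n_volumes=n_total, paradigm="block",
                          regressor=reg, boxcar=box)


def band_limited_noise(
    n_volumes: int,
    tr: float,
    rng: np.random.Generator,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
) -> np.ndarray:
    """Gaussian time course band-limited to [f_lo, f_hi] Hz, unit sd.

    Implemented by masking the rFFT of white noise; this is the latent
    "resting-state fluctuation" model for each network.
    """
    white = rng.standard_normal(n_volumes)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n=n_volumes)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def _ar1_noise(shape: tuple[int, ...], ar1: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """AR(1) Gaussian noise along the last axis with marginal sd ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - ar1 ** 2) if ar1 > 0 else sd
    e = rng.standard_normal(shape) * innov_sd
    if ar1 == 0:
        return e
    # stationary start, then x_t = ar1 x_{t-1} + e_t
    e[..., 0] = rng.standard_normal(shape[:-1]) * sd
    return sps.lfilter([1.0], [1.0, -ar1], e, axis=-1)


def simulate_subject(
    atlas: AtlasSet,
    design: StimulusDesign,
    group: str,
    effect: EffectSpec,
    seed: int,
    subject_id: str | None = None,
    amplitude: float = 1.0,
    baseline: float = 100.0,
    rest_fluctuation_sd: float = 0.2,
) -> BoldSeries:
    """Simulate one subject's 4D BOLD run on the phantom atlas.

    Every network carries one shared latent time course: band-limited
    Gaussian noise at rest, or the design regressor plus a small
    band-limited fluctuation for block designs.  Voxel signal is
    ``baseline + amplitude x jitter x structure_factor x latent + AR(1) noise``.
    Injury factors from ``effect`` apply only when ``group == "injured"``.
    """
    if group not in ("control", "injured"):
        raise ValueError("group must be 'control' or 'injured'")
    rng = np.random.default_rng(seed)
    T = design.n_volumes
    dims = atlas.label_volume.shape
    data = np.zeros(dims + (T,), dtype=np.float64)
    data[atlas.brain_mask] = baseline

    # one latent course + one amplitude jitter per network, shared by its
    # structures -- this is what makes networks recoverable by decomposition
    latents: dict[str, np.ndarray] = {}
    jitters: dict[str, float] = {}
    for net in NETWORK_NAMES:
        if design.paradigm == "rest":
            latents[net] = band_limited_noise(T, design.tr, rng)
        else:
            latents[net] = design.regressor + rest_fluctuation_sd * \
                band_limited_noise(T, design.tr, rng)
        jitters[net] = float(np.exp(effect.amplitude_jitter *
                                    rng.standard_normal()))

    for _label, name, net in atlas.structures:
        mask = atlas.label_volume == _label
        f = effect.factor(name) if group == "injured" else 1.0
        course = amplitude * jitters[net] * f * latents[net]
        data[mask] += course[None, :]

    if effect.noise_sd > 0:
        n_brain = int(atlas.brain_mask.sum())
        noise = _ar1_noise((n_brain, T), effect.ar1, effect.noise_sd, rng)
        data[atlas.brain_mask] += noise

    if subject_id is None:
        subject_id = f"{group[:3]}-{seed}"
    return BoldSeries(data=data, tr=design.tr, brain_mask=atlas.brain_mask.copy(),
                      subject_id=subject_id, group=group)
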