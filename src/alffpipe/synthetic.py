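"""Synthetic resting-state cohorts with known ground truth.

Each subject's 4D series is, per voxel, a sum of three parts:

* an oscillatory component: ``n_lfo`` cosines with frequencies drawn
  uniformly in the low-frequency band and uniform random phases, unit base
  amplitude. Group differences are planted *multiplicatively* on this
  amplitude inside chosen regions (an ``amplitude_ratio`` of 1.5 means group
  A oscillates 1.5x stronger there) — exactly the quantity ALFF measures;
* stationary AR(1) noise (white noise ``sigma_white``, lag-1 correlation
  ``ar1_rho``), supplying broadband power inside and outside the band;
* a 1/f-shaped drift component made by spectrally shaping white noise
  (amplitude ∝ f^(-1/2) on the DFT bins), emulating residual slow scanner
  and physiological drift after detrending.

Gray-matter covariate maps are baseline + between-subject Gaussian noise,
with a fractional reduction for group A inside an atrophy region so that
covariate adjustment can be exercised. Per-subject brain masks are the full
grid minus a small random erosion of the boundary shell, so the intersection
mask genuinely differs from any single subject's mask.

Defaults mirror the acquisition this emulates: TR = 3 s, 124 volumes,
20 vs 18 subjects. The grid defaults to 24x24x16 at 3 mm — a desk-scale
stand-in for a normalized EPI grid; the acquisition-sized grid is a config
choice away. Everything is reproducible from ``(spec, seed)`` via a stable
seed hierarchy: subject i uses ``SeedSequence((spec.seed, i))``.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
import yaml

from .image_io import (
    BrainMask,
    ScalarMap,
    TimeSeriesImage,
    VoxelGrid,
    write_mask,
    write_map,
    write_timeseries,
)

__all__ = [
    "NoiseSpec",
    "EffectSpec",
    "GmSpec",
    "CohortSpec",
    "Subject",
    "CohortDataset",
    "box_roi",
    "generate_subject_timeseries",
    "generate_cohort",
    "materialize_cohort",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise mixture for one voxel's series; see the module docstring."""

    sigma_white: float = 1.0
    ar1_rho: float = 0.3
    one_over_f_scale: float = 0.25
    n_lfo: int = 5
    lfo_band: tuple[float, float] = (0.01, 0.08)

    def __post_init__(self) -> None:
        if self.sigma_white < 0:  # 0 = noise-free limit, useful for testing
            raise ValueError("sigma_white must be >= 0")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.one_over_f_scale < 0 or self.n_lfo < 0:
            raise ValueError("amplitudes and counts must be >= 0")
        if not (0.0 < self.lfo_band[0] <= self.lfo_band[1]):
            # low == high pins every oscillation to one frequency
            raise ValueError("lfo_band must satisfy 0 < low <= high")


@dataclass(frozen=True)
class EffectSpec:
    """A planted group difference: in-band amplitude scaled in group A."""

    roi: BrainMask
    amplitude_ratio: float

    def __post_init__(self) -> None:
        if not self.amplitude_ratio > 0:
            raise ValueError("amplitude_ratio must be > 0")


@dataclass(frozen=True)
class GmSpec:
    """Gray-matter covariate maps, with optional planted group-A atrophy."""

    baseline: float = 0.6
    atrophy_roi: BrainMask | None = None
    group_a_deficit: float = 0.0
    subject_sd: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.group_a_deficit < 1.0):
            raise ValueError("group_a_deficit must be in [0, 1)")
        if self.group_a_deficit > 0 and self.atrophy_roi is None:
            raise ValueError("group_a_deficit > 0 requires an atrophy_roi")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")


def _default_grid() -> VoxelGrid:
    return VoxelGrid.isotropic((24, 24, 16), 3.0)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a cohort deterministically."""

    n_group_a: int = 20
    n_group_b: int = 18
    grid: VoxelGrid = field(default_factory=_default_grid)
    nt: int = 124
    tr: float = 3.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    effects: tuple[EffectSpec, ...] = ()
    gm_confound: GmSpec = field(default_factory=GmSpec)
    mask_erosion_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.nt < 16:
            raise ValueError("need at least 16 volumes")
        if not self.tr > 0:
            raise ValueError("TR must be positive")
        object.__setattr__(self, "effects", tuple(self.effects))
        for e in self.effects:
            if e.roi.grid.shape != self.grid.shape:
                raise ValueError("effect ROI grid does not match the cohort grid")

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b


@dataclass
class Subject:
    subject_id: str
    group: str
    bold: TimeSeriesImage
    gm: ScalarMap
    mask: BrainMask


@dataclass
class CohortDataset:
    subjects: list[Subject]
    truth: tuple[EffectSpec, ...]
    spec: CohortSpec

    def group_labels(self) -> list[str]:
        return [s.group for s in self.subjects]


def box_roi(grid: VoxelGrid, center: tuple[int, int, int],
            size: tuple[int, int, int]) -> BrainMask:
    """A rectangular ROI of the given voxel extents, clipped to the grid."""
    m = np.zeros(grid.shape, dtype=bool)
    sl = tuple(
        slice(max(c - s // 2, 0), min(c - s // 2 + s, n))
        for c, s, n in zip(center, size, grid.shape)
    )
    m[sl] = True
    return BrainMask(grid, m)


def _subject_rng(spec_seed: int, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec_seed, subject_seed)))


def _ar1(rng: np.random.Generator, n_series: int, nt: int,
         rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) rows: x_t = rho x_{t-1} + e_t, e ~ N(0, sigma^2)."""
    e = rng.standard_normal((n_series, nt)) * sigma
    if rho == 0.0:
        return e
    # start each row from its stationary distribution, fed in via the filter state
    x0 = rng.standard_normal(n_series) * sigma / np.sqrt(1.0 - rho**2)
    e[:, 0] = 0.0  # first sample is the stationary draw itself
    out, _ = scipy.signal.lfilter([1.0], [1.0, -rho], e, axis=1, zi=x0[:, None])
    return out


def _one_over_f(rng: np.random.Generator, n_series: int, nt: int,
                tr: float, scale: float) -> np.ndarray:
    """1/f-shaped noise: white noise with DFT amplitudes scaled by f^(-1/2)."""
    if scale == 0.0:
        return np.zeros((n_series, nt))
    w = rng.standard_normal((n_series, nt))
    spec = np.fft.rfft(w, axis=1)
    f = np.fft.rfftfreq(nt, tr)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** -0.5
    return np.fft.irfft(spec * shape[None, :], nt, axis=1) * scale


def generate_subject_timeseries(
    spec: CohortSpec, group: str, subject_seed: int
) -> TimeSeriesImage:
    """One subject's 4D series; bit-reproducible from (spec.seed, subject_seed)."""
    ns = spec.noise
    nv = int(np.prod(spec.grid.shape))
    rng = _subject_rng(spec.seed, subject_seed)
    t = np.arange(spec.nt) * spec.tr

    amp = np.ones(nv)
    if group == "A":
        for eff in spec.effects:
            amp[eff.roi.data.ravel()] *= eff.amplitude_ratio

    sig = np.zeros((nv, spec.nt), dtype=np.float32)
    if ns.n_lfo > 0:
        freqs = rng.uniform(*ns.lfo_band, size=(nv, ns.n_lfo))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(nv, ns.n_lfo))
        # the sinusoid bank is evaluated in float32: ~5x faster, and the
        # ~1e-7 relative trig error is far below every other noise source
        t32 = t.astype(np.float32)
        f32 = (2.0 * np.pi * freqs).astype(np.float32)
        p32 = phases.astype(np.float32)
        osc = sig  # accumulate in place, one (nv, nt) block at a time
        for j in range(ns.n_lfo):
            osc += np.cos(f32[:, j, None] * t32[None, :] + p32[:, j, None])
        sig *= amp[:, None].astype(np.float32)

    sig += _ar1(rng, nv, spec.nt, ns.ar1_rho, ns.sigma_white).astype(np.float32)
    sig += _one_over_f(rng, nv, spec.nt, spec.tr, ns.one_over_f_scale).astype(np.float32)
    return TimeSeriesImage(spec.grid, sig.reshape(*spec.grid.shape, spec.nt), spec.tr)


def _subject_mask(spec: CohortSpec, rng: np.random.Generator) -> BrainMask:
    """Full grid minus a random thinning of the one-voxel boundary shell."""
    m = np.ones(spec.grid.shape, dtype=bool)
    interior = np.zeros_like(m)
    interior[1:-1, 1:-1, 1:-1] = True
    shell = m & ~interior
    drop = shell & (rng.random(m.shape) < spec.mask_erosion_prob)
    m[drop] = False
    return BrainMask(spec.grid, m)


def _subject_gm(spec: CohortSpec, group: str, rng: np.random.Generator) -> ScalarMap:
    g = spec.gm_confound
    data = np.full(spec.grid.shape, g.baseline, dtype=np.float64)
    if group == "A" and g.group_a_deficit > 0:
        data[g.atrophy_roi.data] *= 1.0 - g.group_a_deficit
    if g.subject_sd > 0:
        data += rng.standard_normal(spec.grid.shape) * g.subject_sd
    return ScalarMap(spec.grid, data, kind="gm")


def cohort_layout(spec: CohortSpec) -> list[tuple[int, str, str]]:
    """(subject index, subject id, group) for every subject, A first then B.

    The subject seed equals the subject's index, so adding subjects at the
    end never changes earlier subjects' data.
    """
    labels = ["A"] * spec.n_group_a + ["B"] * spec.n_group_b
    out = []
    counts = {"A": 0, "B": 0}
    for idx, group in enumerate(labels):
        counts[group] += 1
        out.append((idx, f"sub-{group}{counts[group]:02d}", group))
    return out


def generate_subject_sidecar(
    spec: CohortSpec, group: str, subject_seed: int
) -> tuple[BrainMask, ScalarMap]:
    """The subject's brain mask and gray-matter map (independent rng stream)."""
    side = np.random.default_rng(np.random.SeedSequence((spec.seed, subject_seed, 1)))
    return _subject_mask(spec, side), _subject_gm(spec, group, side)


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """All subjects of both groups, with ground truth attached."""
    subjects: list[Subject] = []
    for idx, sid, group in cohort_layout(spec):
        bold = generate_subject_timeseries(spec, group, idx)
        mask, gm = generate_subject_sidecar(spec, group, idx)
        subjects.append(Subject(sid, group, bold, gm, mask))
    return CohortDataset(subjects=subjects, truth=spec.effects, spec=spec)


# ---------------------------------------------------------------------------
# On-disk form: NIfTI files + TSV manifest + YAML ground-truth sidecar


def materialize_cohort(ds: CohortDataset, out_dir: os.PathLike | str) -> str:
    """Write the cohort as NIfTI files with a TSV manifest; returns the manifest path."""
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    rows = []
    for s in ds.subjects:
        paths = {
            "bold_path": os.path.join(out, f"{s.subject_id}_bold.nii.gz"),
            "gm_path": os.path.join(out, f"{s.subject_id}_gm.nii.gz"),
            "mask_path": os.path.join(out, f"{s.subject_id}_mask.nii.gz"),
        }
        write_timeseries(s.bold, paths["bold_path"])
        write_map(s.gm, paths["gm_path"])
        write_mask(s.mask, paths["mask_path"])
        rows.append({"subject_id": s.subject_id, "group": s.group, **paths})
    manifest = os.path.join(out, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    truth = {
        "seed": ds.spec.seed,
        "n_group_a": ds.spec.n_group_a,
        "n_group_b": ds.spec.n_group_b,
        "nt": ds.spec.nt,
        "tr": ds.spec.tr,
        "effects": [
            {"amplitude_ratio": e.amplitude_ratio, "roi_n_voxels": e.roi.n_voxels}
            for e in ds.truth
        ],
    }
    with open(os.path.join(out, "truth.yaml"), "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return manifest


def cohort_fingerprint(ds: CohortDataset) -> str:
    """SHA-256 over all subject arrays; equal iff the cohorts are bit-identical."""
    h = hashlib.sha256()
    for s in ds.subjects:
        h.update(s.subject_id.encode())
        h.update(s.bold.data.tobytes())
        h.update(s.gm.data.tobytes())
        h.update(s.mask.data.tobytes())
    return h.hexdigest()
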