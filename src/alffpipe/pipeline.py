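"""End-to-end orchestration: cohort -> ALFF -> GLM -> cluster correction.

Stages, in order:

1. load subjects from a TSV manifest, or generate a synthetic cohort;
2. intersect the per-subject brain masks into the analysis mask;
3. per subject: linear detrend, ALFF over the low-frequency band,
   standardization by the global mean within the analysis mask;
4. spatial smoothing of the standardized maps (FWHM defaulting to the
   cluster-correction FWHM, so the smoothness the Monte-Carlo null assumes
   is the smoothness the analyzed maps actually have); configurable off;
5. voxelwise GLM of group with the gray-matter covariate;
6. Monte-Carlo estimation of the null largest-cluster distribution and the
   extent threshold at the corrected alpha; cluster-extent correction of the
   t-map; cluster table in the direction/size/peak-t/peak-mm shape.

Every artifact (maps, null distribution, table, run record, log) is written
under the output directory when one is given, and every reported number is
recomputable from those artifacts.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alff import BandSpec, alff_maps
from .cluster import (
    ClusterSimParams,
    apply_cluster_correction,
    cluster_extent_threshold,
    simulate_max_cluster_null,
    smooth_map,
)
from .glm import build_design, fit_voxelwise_glm
from .image_io import (
    BrainMask,
    ScalarMap,
    intersect_masks,
    read_map,
    read_mask,
    read_timeseries,
    write_map,
    write_mask,
)
from .synthetic import (
    CohortSpec,
    Subject,
    cohort_layout,
    generate_subject_sidecar,
    generate_subject_timeseries,
)

__all__ = [
    "PipelineConfig",
    "ClusterReport",
    "load_cohort_manifest",
    "run_pipeline",
    "write_cluster_table",
    "read_cluster_table",
    "paper_default_config",
]

log = logging.getLogger(__name__)

#: analysis parameters as printed in the source study
PAPER_DEFAULTS = {
    "band": (0.01, 0.08),   # Hz
    "voxel_p": 0.05,
    "corrected_alpha": 0.01,
    "fwhm_mm": 8.0,
}

TABLE_COLUMNS = ["direction", "size_voxels", "size_mm3", "peak_t", "x_mm", "y_mm", "z_mm"]


@dataclass
class PipelineConfig:
    """All knobs of one run; defaults are the source study's parameters."""

    cohort: CohortSpec | None = None
    manifest: str | None = None
    tr_override: float | None = None
    band: BandSpec = field(default_factory=BandSpec)
    detrend: bool = True
    covariate_mode: str = "voxelwise"       # voxelwise | global | none
    smooth_fwhm_mm: float | None = None     # None -> fwhm_mm
    voxel_p: float = 0.05
    corrected_alpha: float = 0.01
    fwhm_mm: float = 8.0
    connectivity: int = 26
    two_tailed: bool = True
    n_iter: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise ValueError("give exactly one of cohort / manifest")
        if self.covariate_mode not in ("voxelwise", "global", "none"):
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")

    @property
    def effective_smooth_fwhm(self) -> float:
        return self.fwhm_mm if self.smooth_fwhm_mm is None else self.smooth_fwhm_mm


def paper_default_config(**overrides) -> PipelineConfig:
    """A config preloaded with the study's printed analysis parameters."""
    base = dict(
        band=BandSpec(*PAPER_DEFAULTS["band"]),
        voxel_p=PAPER_DEFAULTS["voxel_p"],
        corrected_alpha=PAPER_DEFAULTS["corrected_alpha"],
        fwhm_mm=PAPER_DEFAULTS["fwhm_mm"],
    )
    base.update(overrides)
    return PipelineConfig(**base)


@dataclass
class ClusterReport:
    """Surviving clusters, one row per cluster, plus the run's key numbers."""

    rows: pd.DataFrame
    extent_voxels: int
    extent_mm3: float
    df: int
    t_crit: float
    analysis_mask_voxels: int

    def overlaps(self, roi: BrainMask, labels: np.ndarray) -> bool:
        """Does any surviving cluster intersect the given ROI?"""
        return bool(np.any((labels > 0) & roi.data))


def load_cohort_manifest(path: str, tr: float | None = None) -> list[Subject]:
    """Read subjects from a TSV manifest (subject_id, group, *_path columns)."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "bold_path", "gm_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    subjects = []
    for rec in df.itertuples(index=False):
        subjects.append(
            Subject(
                subject_id=str(rec.subject_id),
                group=str(rec.group),
                bold=read_timeseries(_resolve(rec.bold_path), tr=tr),
                gm=read_map(_resolve(rec.gm_path), kind="gm"),
                mask=read_mask(_resolve(rec.mask_path)),
            )
        )
    return subjects


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> ClusterReport:
    """Execute the full analysis; see the module docstring for the stages."""
    out = config.out_dir
    handler = None
    if out is not None:
        os.makedirs(out, exist_ok=True)
        handler = logging.FileHandler(os.path.join(out, "pipeline.log"), mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logging.getLogger("alffpipe").addHandler(handler)
        logging.getLogger("alffpipe").setLevel(logging.INFO)
    try:
        return _run(config)
    except Exception:
        raise
    finally:
        if handler is not None:
            logging.getLogger("alffpipe").removeHandler(handler)
            handler.close()


def _run(config: PipelineConfig) -> ClusterReport:
    out = config.out_dir

    _stage("load subjects")
    if config.cohort is not None:
        # synthetic cohorts stream: sidecars (mask, gm) first, then each 4D
        # series is generated, reduced to its ALFF maps, and dropped, so peak
        # memory stays at one subject's series
        spec = config.cohort
        layout = cohort_layout(spec)
        sidecars = [generate_subject_sidecar(spec, g, i) for i, _, g in layout]
        subj_meta = [(sid, g) for _, sid, g in layout]
        masks = [m for m, _ in sidecars]
        gm_list = [g for _, g in sidecars]
        bold_iter = (
            generate_subject_timeseries(spec, g, i) for i, _, g in layout
        )
    else:
        loaded = load_cohort_manifest(config.manifest, tr=config.tr_override)
        subj_meta = [(s.subject_id, s.group) for s in loaded]
        masks = [s.mask for s in loaded]
        gm_list = [s.gm for s in loaded]
        bold_iter = (s.bold for s in loaded)
    if len(subj_meta) < 4:
        raise RuntimeError("stage load subjects: need at least 4 subjects")
    log.info("loaded %d subjects (%s)", len(subj_meta),
             ", ".join(sorted({g for _, g in subj_meta})))

    _stage("intersect masks")
    mask = intersect_masks(masks)
    log.info("analysis mask: %d voxels", mask.n_voxels)

    _stage("per-subject ALFF")
    malff_maps: list[ScalarMap] = []
    for (sid, _), bold in zip(subj_meta, bold_iter):
        try:
            res = alff_maps(bold, mask, config.band, detrend=config.detrend)
        except Exception as exc:  # re-raise with subject context
            raise RuntimeError(f"stage ALFF failed for {sid}: {exc}") from exc
        malff_maps.append(res.malff)
        log.info("%s: global mean ALFF %.4f over %d band bins",
                 sid, res.global_mean, res.n_bins)

    sm_fwhm = config.effective_smooth_fwhm
    if sm_fwhm > 0:
        _stage("spatial smoothing")
        log.info("smoothing standardized maps at FWHM %.1f mm", sm_fwhm)
        malff_maps = [smooth_map(m, sm_fwhm) for m in malff_maps]

    _stage("group GLM")
    groups = [g for _, g in subj_meta]
    if config.covariate_mode == "voxelwise":
        design = build_design(groups)
        glm = fit_voxelwise_glm(malff_maps, design, mask, voxelwise_covariate=gm_list)
    elif config.covariate_mode == "global":
        gm_totals = np.array([float(g.data[mask.data].mean()) for g in gm_list])
        design = build_design(groups, covariates={"gm": gm_totals})
        glm = fit_voxelwise_glm(malff_maps, design, mask)
    else:
        design = build_design(groups)
        glm = fit_voxelwise_glm(malff_maps, design, mask)
    log.info("GLM df=%d, %d rank-deficient voxels", glm.df, glm.n_flagged)

    _stage("Monte-Carlo cluster null")
    mc_seed = int(np.random.SeedSequence((config.seed, 0xA1FF)).generate_state(1)[0] % (2**31))
    params = ClusterSimParams(
        mask=mask,
        fwhm_mm=config.fwhm_mm,
        voxel_p=config.voxel_p,
        two_tailed=config.two_tailed,
        connectivity=config.connectivity,
        n_iter=config.n_iter,
        seed=mc_seed,
    )
    dist = simulate_max_cluster_null(params)
    extent, extent_mm3 = cluster_extent_threshold(dist, config.corrected_alpha)
    log.info("extent threshold: %d voxels (%.0f mm3) at corrected alpha %.3g",
             extent, extent_mm3, config.corrected_alpha)

    _stage("cluster correction")
    clusters = apply_cluster_correction(
        glm.tmap, glm.df, config.voxel_p, extent,
        mask=mask, connectivity=config.connectivity, two_tailed=config.two_tailed,
    )
    pos = f"{design.positive_label}_gt_{design.negative_label}"
    neg = f"{design.negative_label}_gt_{design.positive_label}"
    rows = pd.DataFrame(
        [
            {
                "direction": pos if d == "pos" else neg,
                "size_voxels": int(sz),
                "size_mm3": float(sz * mask.grid.voxel_volume_mm3),
                "peak_t": float(pk[0]),
                "x_mm": float(pk[1][0]),
                "y_mm": float(pk[1][1]),
                "z_mm": float(pk[1][2]),
            }
            for d, sz, pk in zip(clusters.directions, clusters.sizes, clusters.peaks)
        ],
        columns=TABLE_COLUMNS,
    )
    import scipy.stats

    report = ClusterReport(
        rows=rows,
        extent_voxels=extent,
        extent_mm3=extent_mm3,
        df=glm.df,
        t_crit=float(scipy.stats.t.isf(
            config.voxel_p / 2 if config.two_tailed else config.voxel_p, glm.df)),
        analysis_mask_voxels=mask.n_voxels,
    )
    report.cluster_labels = clusters.labels  # for overlap queries downstream

    if out is not None:
        _stage("write artifacts")
        write_mask(mask, os.path.join(out, "analysis_mask.nii.gz"))
        write_map(glm.tmap, os.path.join(out, "tmap.nii.gz"))
        write_map(glm.pmap, os.path.join(out, "pmap.nii.gz"))
        for (sid, _), m in zip(subj_meta, malff_maps):
            write_map(m, os.path.join(out, f"{sid}_malff.nii.gz"))
        dist.to_tsv(os.path.join(out, "null_max_cluster.tsv"))
        write_cluster_table(report, os.path.join(out, "cluster_table.tsv"))
        record = {
            "alffpipe_version": __version__,
            "seed": config.seed,
            "band_hz": [config.band.low_hz, config.band.high_hz],
            "detrend": config.detrend,
            "covariate_mode": config.covariate_mode,
            "smooth_fwhm_mm": sm_fwhm,
            "voxel_p": config.voxel_p,
            "corrected_alpha": config.corrected_alpha,
            "fwhm_mm": config.fwhm_mm,
            "connectivity": config.connectivity,
            "two_tailed": config.two_tailed,
            "n_iter": config.n_iter,
            "mc_seed": mc_seed,
            "df": glm.df,
            "t_crit": report.t_crit,
            "extent_voxels": extent,
            "extent_mm3": extent_mm3,
            "analysis_mask_voxels": mask.n_voxels,
            "n_subjects": len(subj_meta),
        }
        with open(os.path.join(out, "run_record.yaml"), "w") as fh:
            yaml.safe_dump(record, fh, sort_keys=False)
    return report


def annotate_regions(report: ClusterReport, label_map: ScalarMap,
                     lookup_tsv: str) -> ClusterReport:
    """Attach anatomical names to cluster rows from a user-supplied atlas.

    ``label_map`` is an integer-valued volume on the analysis grid and
    ``lookup_tsv`` a two-column TSV (label, region). Each cluster gets the
    region of its peak voxel, or "n/a" when the peak's label is absent from
    the lookup. No atlas ships with the package: atlas choice and version
    are the user's responsibility.
    """
    lut = pd.read_csv(lookup_tsv, sep="\t")
    if not {"label", "region"} <= set(lut.columns):
        raise ValueError(f"{lookup_tsv} must have columns 'label' and 'region'")
    mapping = dict(zip(lut["label"].astype(int), lut["region"].astype(str)))
    inv = np.linalg.inv(label_map.grid.affine)
    regions = []
    for rec in report.rows.itertuples(index=False):
        world = np.array([rec.x_mm, rec.y_mm, rec.z_mm, 1.0])
        ijk = np.round(inv @ world)[:3].astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.asarray(label_map.grid.shape)):
            regions.append("n/a")  # peak outside the atlas volume
            continue
        lab = int(round(float(label_map.data[tuple(ijk)])))
        regions.append(mapping.get(lab, "n/a"))
    rows = report.rows.copy()
    rows["region"] = regions
    out = ClusterReport(rows=rows, extent_voxels=report.extent_voxels,
                        extent_mm3=report.extent_mm3, df=report.df,
                        t_crit=report.t_crit,
                        analysis_mask_voxels=report.analysis_mask_voxels)
    if hasattr(report, "cluster_labels"):
        out.cluster_labels = report.cluster_labels
    return out


def write_cluster_table(report: ClusterReport, path) -> None:
    """TSV cluster table: t at 3 decimals, sizes as integers, coords at 1 dp."""
    has_region = "region" in report.rows.columns
    cols = TABLE_COLUMNS + (["region"] if has_region else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in report.rows.itertuples(index=False):
            fh.write(
                f"{rec.direction}\t{int(rec.size_voxels)}\t{int(round(rec.size_mm3))}\t"
                f"{rec.peak_t:.3f}\t{rec.x_mm:.1f}\t{rec.y_mm:.1f}\t{rec.z_mm:.1f}"
                + (f"\t{rec.region}" if has_region else "") + "\n"
            )


def read_cluster_table(path) -> pd.DataFrame:
    # keep_default_na off: "n/a" region labels are literal strings
    return pd.read_csv(path, sep="\t", keep_default_na=False)
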