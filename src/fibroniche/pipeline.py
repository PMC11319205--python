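"""End-to-end orchestration from a single validated config.

Stages run in dependency order — simulate/read → QC → factorize →
F^hi/subcluster → geometry → enrichment/distance-correlation →
colocalization → pseudobulk — each writing its tabular outputs plus a JSON
manifest (parameters, seed, input hashes). Reruns with an identical config
produce byte-identical outputs.

The demo profile runs entirely on synthetic data: four simulated sections
(two "case" with a planted fibrotic focus, two "control" without), so the
enrichment, colocalization and case-vs-control pseudobulk stages all have
meaningful inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coloc, enrichment, factors, geometry, pseudobulk, qc, synth
from .io import write_results
from .synth import FOCUS_LABEL

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run config fails validation (before any compute)."""


@dataclass
class SimParams:
    n_rows: int = 30
    n_cols: int = 30
    n_genes: int = 150
    k_true: int = 5
    library_size_mean: float = 5000.0
    n_case: int = 2
    n_control: int = 2
    focus_radius_um: float = 300.0


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "fibroniche_run"
    sim: SimParams = field(default_factory=SimParams)
    qc_preset: str = "human"
    min_umis_per_spot: int | None = None
    nmf_k: int = 5
    fhi_percentile: float = 95.0
    subcluster_pcs: int = 8
    subcluster_resolution: float = 0.4
    subcluster_neighbors: int = 10
    roi_label: str = FOCUS_LABEL
    enrichment_k: int = 100
    bin_width_um: float = 100.0
    max_distance_um: float = 3000.0
    distcorr_max_um: float = 500.0
    distcorr_n_variable: int = 100
    compartment_h: float = 1.5
    compartment_linkage: str = "complete"
    jaccard_top_n: int = 50
    de_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim_raw = raw.pop("sim", {})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.sim = SimParams(**sim_raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.qc_preset not in qc.PRESETS:
            raise ConfigError(f"unknown qc preset {self.qc_preset!r}")
        if self.nmf_k < 1:
            raise ConfigError("nmf_k must be >= 1")
        if not 0 < self.fhi_percentile < 100:
            raise ConfigError("fhi_percentile must be in (0, 100)")
        if self.enrichment_k < 2:
            raise ConfigError("enrichment_k must be >= 2")
        if self.compartment_linkage not in {"complete", "average"}:
            raise ConfigError("compartment_linkage must be 'complete' or 'average'")
        if not self.roi_label:
            raise ConfigError("roi_label must be set")


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(stage_dir: Path, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "params": params,
        "input_hashes": {p.name: _hash(p) for p in inputs if p.exists()},
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def simulate_cohort(cfg: RunConfig):
    """Simulate the demo cohort: case sections carry a planted focus
    region, control sections do not."""
    s = cfg.sim
    grids, counts, dens, anns, conditions = [], [], [], [], {}
    pitch = synth.DEFAULT_PITCH_UM
    center = ((s.n_cols - 1) * pitch / 2.0, (s.n_rows - 1) * pitch * 0.866 / 2.0)
    for i in range(s.n_case + s.n_control):
        is_case = i < s.n_case
        sid = f"{'case' if is_case else 'control'}_{i + 1}"
        regions = [synth.Region(cfg.roi_label, center, s.focus_radius_um)] if is_case else []
        g, c, d, a, _ = synth.simulate_section(
            n_rows=s.n_rows, n_cols=s.n_cols, n_genes=s.n_genes, k=s.k_true,
            region_spec=regions, library_size_mean=s.library_size_mean,
            seed=cfg.seed + i, sample_id=sid,
        )
        grids.append(g)
        counts.append(c)
        dens.append(d)
        anns.append(a)
        conditions[sid] = "case" if is_case else "control"
    return (
        pd.concat(grids),
        pd.concat(counts),
        pd.concat(dens),
        pd.concat(anns),
        pd.Series(conditions, name="condition"),
    )


def run_pipeline(cfg: RunConfig, out_dir: Path | None = None) -> Path:
    """Execute all stages; returns the artifact directory."""
    cfg.validate()
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    # --- simulate -------------------------------------------------------
    d = stage("simulate")
    grid, counts, densities, annotation, conditions = simulate_cohort(cfg)
    p_counts = write_results(counts, d / "counts.tsv")
    write_results(grid, d / "grid.tsv")
    write_results(densities, d / "densities.tsv")
    write_results(annotation.to_frame(), d / "annotation.tsv")
    _manifest(d, {"seed": cfg.seed, **asdict(cfg.sim)}, [])

    # --- qc -------------------------------------------------------------
    d = stage("qc")
    thresholds = qc.PRESETS[cfg.qc_preset]
    if cfg.min_umis_per_spot is not None:
        from dataclasses import replace

        thresholds = replace(thresholds, min_umis_per_spot=cfg.min_umis_per_spot)
    filtered, report = qc.filter_matrix(counts, thresholds)
    norm = qc.normalize_log_cp10k(filtered)
    write_results(norm, d / "normalized.tsv")
    write_results(report, d / "qc_report.json", format="json")
    _manifest(d, {"preset": cfg.qc_preset, **asdict(thresholds)}, [p_counts])

    # --- factorize ------------------------------------------------------
    d = stage("factorize")
    model = factors.fit_nmf(norm, k=cfg.nmf_k, seed=cfg.seed)
    write_results(model.activities, d / "activities.tsv")
    write_results(model.loadings, d / "loadings.tsv")
    ranking = factors.top_factor_genes(model, n=cfg.jaccard_top_n)
    write_results(
        {f: list(t.index) for f, t in ranking.per_factor.items()},
        d / "top_genes.json", format="json",
    )
    _manifest(d, {"k": cfg.nmf_k, "seed": cfg.seed, "n_iter": model.n_iter}, [])

    # --- fhi + subcluster ----------------------------------------------
    d = stage("fhi")
    grid_qc = grid.loc[norm.index]
    roi_spots = annotation.index[annotation == cfg.roi_label].intersection(norm.index)
    if len(roi_spots) == 0:
        raise ConfigError(f"no spots annotated {cfg.roi_label!r} survive QC")
    # niche factor = the factor whose activity is most elevated in the ROI
    roi_mean = model.activities.loc[roi_spots].mean()
    rest_mean = model.activities.drop(index=roi_spots).mean()
    niche_factor = (roi_mean - rest_mean).idxmax()
    fhi = factors.select_high_spots(model, niche_factor, q=cfg.fhi_percentile)
    sub_labels = factors.subcluster_spots(
        norm.loc[fhi], n_pcs=cfg.subcluster_pcs,
        resolution=cfg.subcluster_resolution,
        n_neighbors=min(cfg.subcluster_neighbors, max(2, len(fhi) - 1)),
        seed=cfg.seed,
    )
    write_results(sub_labels.to_frame(), d / "subclusters.tsv")
    write_results(
        {"niche_factor": niche_factor, "n_fhi": len(fhi), "fhi": sorted(fhi)},
        d / "fhi.json", format="json",
    )
    _manifest(d, {"factor": niche_factor, "percentile": cfg.fhi_percentile}, [])

    # --- geometry -------------------------------------------------------
    d = stage("geometry")
    graph = geometry.build_adjacency(grid_qc)
    fld = geometry.radial_distance_field(grid_qc, set(roi_spots), graph=graph)
    bins = geometry.assign_distance_bins(
        fld, bin_width_um=cfg.bin_width_um, max_distance_um=cfg.max_distance_um
    )
    write_results(fld, d / "distance_field.tsv")
    write_results(bins.to_frame(), d / "bins.tsv")
    _manifest(d, {"roi_label": cfg.roi_label, "bin_width_um": cfg.bin_width_um,
                  "max_distance_um": cfg.max_distance_um}, [])

    # --- enrichment -----------------------------------------------------
    d = stage("enrichment")
    labels = pd.Series(None, index=norm.index, dtype=object)
    labels.loc[fhi] = "Fhi"
    params = enrichment.EnrichmentParams(
        k=cfg.enrichment_k, bin_width_um=cfg.bin_width_um,
        max_distance_um=cfg.max_distance_um, seed=cfg.seed,
    )
    # bins only exist for samples containing the ROI; shuffle within those
    case_samples = grid_qc.loc[bins.index, "sample_id"].unique()
    labels_case = labels[grid_qc["sample_id"].isin(case_samples).reindex(labels.index, fill_value=False)]
    table = enrichment.border_enrichment_test(bins, labels_case, grid_qc["sample_id"], params)
    write_results(table, d / "enrichment.tsv")
    _manifest(d, {"k": cfg.enrichment_k, "seed": cfg.seed, "p_model": params.p_model}, [])

    # --- distance correlation ------------------------------------------
    d = stage("distcorr")
    dc = enrichment.correlate_with_distance(
        norm, fld, max_distance_um=cfg.distcorr_max_um,
        n_variable=cfg.distcorr_n_variable,
    )
    write_results(dc, d / "distance_correlation.tsv")
    _manifest(d, {"max_distance_um": cfg.distcorr_max_um,
                  "n_variable": cfg.distcorr_n_variable}, [])

    # --- colocalization -------------------------------------------------
    d = stage("coloc")
    dens_qc = densities.loc[norm.index]
    corr = coloc.factor_celltype_correlation(model, dens_qc)
    partition = coloc.celltype_compartments(
        dens_qc, h=cfg.compartment_h, linkage_method=cfg.compartment_linkage
    )
    scores = coloc.compartment_scores(dens_qc, partition)
    write_results(corr, d / "factor_celltype_correlation.tsv")
    write_results(partition.assignments.to_frame(), d / "compartments.tsv")
    write_results(scores, d / "compartment_scores.tsv")
    # cross-"species" comparison: factorize the control arm separately and
    # match factors by top-gene Jaccard (identity gene map)
    control_spots = grid_qc.index[grid_qc["sample_id"].str.startswith("control")]
    jac = None
    if len(control_spots) > cfg.nmf_k:
        model_b = factors.fit_nmf(norm.loc[control_spots], k=cfg.nmf_k, seed=cfg.seed)
        ranking_b = factors.top_factor_genes(model_b, n=cfg.jaccard_top_n)
        jac = coloc.cross_factor_jaccard(ranking, ranking_b)
        write_results(jac, d / "factor_jaccard.tsv")
    _manifest(d, {"h": cfg.compartment_h, "linkage": cfg.compartment_linkage}, [])

    # --- pseudobulk -----------------------------------------------------
    d = stage("pseudobulk")
    pb = pseudobulk.aggregate_pseudobulk(filtered, grid_qc["sample_id"])
    de = pseudobulk.simple_de(pb, conditions)
    write_results(pb, d / "pseudobulk.tsv")
    write_results(de.table, d / "de.tsv")
    n_sig = int((de.table["p_adj"] < cfg.de_alpha).sum())
    _manifest(d, {"alpha": cfg.de_alpha, "n_significant": n_sig}, [])

    # --- summary --------------------------------------------------------
    bin0 = table[(table["bin"] == 0) & (table["cluster"] == "Fhi")]
    inside = table[(table["bin"] == -1) & (table["cluster"] == "Fhi")]
    summary = {
        "enrichment_z_inside": float(inside["z"].iloc[0]) if len(inside) else None,
        "enrichment_p_inside": float(inside["p"].iloc[0]) if len(inside) else None,
        "niche_factor": niche_factor,
        "n_spots_qc": int(norm.shape[0]),
        "n_genes_qc": int(norm.shape[1]),
        "n_fhi": int(len(fhi)),
        "n_subclusters": int(sub_labels.nunique()),
        "enrichment_z_bin0": float(bin0["z"].iloc[0]) if len(bin0) else None,
        "enrichment_p_bin0": float(bin0["p"].iloc[0]) if len(bin0) else None,
        "n_compartments": int(partition.assignments.nunique()),
        "n_de_significant": n_sig,
        "max_jaccard": float(jac["jaccard"].max()) if jac is not None else None,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def demo_config(seed: int = 1, out_dir: str = "fibroniche_demo") -> RunConfig:
    """The synthetic demo profile (runs in well under five minutes)."""
    return RunConfig(seed=seed, out_dir=out_dir)
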