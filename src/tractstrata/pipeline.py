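"""End-to-end cross-sectional and longitudinal analysis orchestration.

Stages, in order: HC length trisection -> per-subject class summaries ->
network topology -> covariate-adjusted group comparisons with FDR ->
volume / network / clinical correlations -> RRMS-vs-NMOSD cross-validated
LDA ROC. The longitudinal run reuses the baseline-HC boundaries and runs
paired tests per patient group.

Multiplicity families mirror how results tables are presented: one family
per group-comparison table, one per correlation table (disease x metric x
feature set), one for the longitudinal outcome set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .classify import CvRocResult, cv_lda_roc
from .datamodel import (
    DEEP_GM_VOLUME_FEATURES,
    GLOBAL_VOLUME_FEATURES,
    CohortManifest,
    ConnectomeTriplet,
    ValidationError,
    VolumeTable,
)
from .netmetrics import network_metrics, threshold_by_sparsity
from .stats import (
    GroupComparison,
    PairedComparison,
    adjust_contrast_family,
    adjust_correlation_family,
    ancova_compare,
    correlate,
    fdr_bh,
    paired_compare,
)
from .stratify import (
    LengthBoundaries,
    classify_edges,
    compute_boundaries,
    hc_average_length,
    summarize,
    summarize_weighted,
)
from .synthetic import SyntheticCohort, SyntheticCohortConfig, generate_cohort, generate_followup

logger = logging.getLogger(__name__)

FN_CLASS_OUTCOMES = ("fn_short", "fn_middle", "fn_long")
FA_CLASS_OUTCOMES = ("fa_short", "fa_middle", "fa_long")
STRATIFIED_OUTCOMES = FN_CLASS_OUTCOMES + FA_CLASS_OUTCOMES
CLASS_OUTCOMES = FN_CLASS_OUTCOMES + ("fn_total",) + FA_CLASS_OUTCOMES
NET_METRIC_COLUMNS = (
    "shortest_path_length",
    "clustering_coefficient",
    "local_efficiency",
    "global_efficiency",
)


@dataclass
class RunConfig:
    """One self-contained analysis run (synthetic or on-disk inputs)."""

    synthetic: SyntheticCohortConfig | None = None
    input_dir: str | None = None
    basis: str = "subject"           # or "hc_average"
    fa_weighting: str = "unweighted"  # or "fn_weighted"
    network_weight: str = "fn"       # or "fa"
    network_weight_mode: str = "max_normalized"
    network_distance: str = "inverse"
    functional_sparsity: float = 0.2
    functional_binarize: bool = True
    alpha: float = 0.05
    roc_k: int = 5
    seed: int = 0
    with_network_metrics: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValidationError(
                "exactly one of synthetic config or input_dir must be set"
            )
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class Cohort:
    """In-memory cohort: triplets keyed by (subject_id, timepoint)."""

    manifest: CohortManifest
    triplets: dict[tuple[str, str], ConnectomeTriplet]
    volumes: VolumeTable | None = None
    functional: dict[str, np.ndarray] | None = None


@dataclass
class ResultBundle:
    boundaries: LengthBoundaries
    summaries: pd.DataFrame
    network: pd.DataFrame | None
    group_comparisons: pd.DataFrame
    volume_correlations: pd.DataFrame
    network_correlations: pd.DataFrame
    clinical_correlations: pd.DataFrame
    roc: CvRocResult | None
    comparisons: list[GroupComparison] = field(default_factory=list)
    sidecar: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "summaries": self.summaries,
            "group_comparisons": self.group_comparisons,
            "volume_correlations": self.volume_correlations,
            "network_correlations": self.network_correlations,
            "clinical_correlations": self.clinical_correlations,
        }
        if self.network is not None:
            out["network_metrics"] = self.network
        if self.roc is not None:
            out["roc"] = pd.DataFrame(
                {"fold": range(len(self.roc.fold_aucs)), "auc": self.roc.fold_aucs}
            )
            out["roc_curves"] = pd.concat(self.roc.roc_curves, ignore_index=True)
        return out

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=False)
        tio.write_sidecar(out / "run_sidecar.json", **self.sidecar)


def load_cohort(config: RunConfig) -> Cohort:
    """Materialize the cohort either from the generator or from disk."""
    if config.synthetic is not None:
        sc = generate_cohort(config.synthetic)
        if sc.config.n_followup_rrms or sc.config.n_followup_nmosd:
            sc = generate_followup(sc)
        return cohort_from_synthetic(sc)
    root = Path(config.input_dir)
    manifest = tio.read_manifest(root / "manifest.csv")
    volumes = None
    if (root / "volumes.csv").exists():
        volumes = tio.read_volume_table(root / "volumes.csv", manifest)
    triplets: dict[tuple[str, str], ConnectomeTriplet] = {}
    functional: dict[str, np.ndarray] = {}
    for r in manifest:
        if not (r.length_path and r.fn_path and r.fa_path):
            raise ValidationError(f"{r.subject_id}: manifest lacks matrix paths")
        trip = tio.read_triplet(
            root / r.length_path, root / r.fn_path, root / r.fa_path,
            root / "node_labels.txt", subject_id=r.subject_id,
        )
        triplets[(r.subject_id, r.timepoint)] = trip
        if r.functional_path:
            functional[r.subject_id] = tio.read_matrix(root / r.functional_path)
    return Cohort(manifest, triplets, volumes, functional or None)


def cohort_from_synthetic(sc: SyntheticCohort) -> Cohort:
    triplets = {(t.subject_id, "baseline"): t for t in sc.triplets}
    triplets.update({(t.subject_id, "followup"): t for t in sc.followup_triplets})
    return Cohort(sc.manifest, triplets, sc.volumes, sc.functional)


def compute_summaries(
    cohort: Cohort,
    basis: str = "subject",
    fa_weighting: str = "unweighted",
) -> tuple[LengthBoundaries, pd.DataFrame]:
    """HC trisection plus one summary row per subject x timepoint.

    Boundaries always come from baseline HC subjects only and are frozen
    for every group and timepoint.
    """
    hc_ids = [r.subject_id for r in cohort.manifest if r.group == "HC" and r.timepoint == "baseline"]
    if not hc_ids:
        raise ValidationError("no baseline HC subjects: cannot derive boundaries")
    hc_triplets = [cohort.triplets[(s, "baseline")] for s in hc_ids]
    avg = hc_average_length(hc_triplets)
    boundaries = compute_boundaries(avg)
    summarizer = summarize if fa_weighting == "unweighted" else summarize_weighted

    rows = []
    for r in cohort.manifest:
        trip = cohort.triplets[(r.subject_id, r.timepoint)]
        mask = classify_edges(trip, boundaries, basis=basis, hc_avg_length=avg)
        s = summarizer(trip, mask)
        row = s.as_dict()
        row.update(
            group=r.group, timepoint=r.timepoint, age=r.age, sex=r.sex,
            edss=r.edss, disease_duration=r.disease_duration,
            t2_lesion_volume=r.t2_lesion_volume,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    logger.info(
        "summaries: %d rows; boundaries [%.2f, %.2f, %.2f, %.2f] mm",
        len(df), boundaries.l_min, boundaries.b1, boundaries.b2, boundaries.l_max,
    )
    return boundaries, df


def compute_network_table(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    """Four global topology metrics per subject, structural (+ functional)."""
    rows = []
    for r in cohort.manifest:
        if r.timepoint != "baseline":
            continue
        trip = cohort.triplets[(r.subject_id, "baseline")]
        W = trip.fn if config.network_weight == "fn" else trip.fa
        m = network_metrics(W, config.network_weight_mode, config.network_distance)
        rows.append(
            dict(subject_id=r.subject_id, group=r.group, network="structural",
                 weight_mode=config.network_weight_mode, sparsity=np.nan,
                 **asdict(m))
        )
        if cohort.functional and r.subject_id in cohort.functional:
            Wf = threshold_by_sparsity(
                cohort.functional[r.subject_id],
                config.functional_sparsity,
                config.functional_binarize,
            )
            mf = network_metrics(Wf, "raw", config.network_distance)
            rows.append(
                dict(subject_id=r.subject_id, group=r.group, network="functional",
                     weight_mode="binary" if config.functional_binarize else "raw",
                     sparsity=config.functional_sparsity, **asdict(mf))
            )
    return pd.DataFrame(rows)


def compare_groups(
    summaries: pd.DataFrame,
    outcomes=STRATIFIED_OUTCOMES,
    covariate_names=("age", "sex"),
) -> tuple[list[GroupComparison], pd.DataFrame]:
    """ANCOVA per outcome over baseline subjects; one FDR family per call.

    The canonical family is the six stratified outcomes (FN and FA for the
    three length classes); total FN is compared in its own family."""
    base = summaries[summaries["timepoint"] == "baseline"]
    comparisons = []
    for outcome in outcomes:
        y = base[outcome].to_numpy(dtype=float)
        cov = base.loc[:, list(covariate_names)] if covariate_names else None
        comparisons.append(
            ancova_compare(y, base["group"].to_numpy(), cov, outcome=outcome)
        )
    adjust_contrast_family(comparisons)
    rows = []
    for gc in comparisons:
        for c in gc.contrasts:
            rows.append(
                dict(outcome=gc.outcome, f_stat=gc.f_stat, p_omnibus=gc.p_omnibus,
                     contrast=f"{c.pair[0]}-{c.pair[1]}", estimate=c.estimate,
                     p=c.p, p_fdr=c.p_fdr, cohens_d=c.cohens_d)
            )
    return comparisons, pd.DataFrame(rows)


def _correlation_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(disease=d, metric=m, feature=r.y, cls=r.x, method=r.method,
                 n=r.n, r=r.r, p=r.p, p_fdr=r.p_fdr)
            for d, m, r in records
        ]
    )


def correlate_volumes(
    summaries: pd.DataFrame, volumes: VolumeTable, method: str = "auto"
) -> pd.DataFrame:
    """Per-disease FN/FA-class vs volume correlations (Tables-3/4 layout).

    FDR families: one per disease x metric x feature set (global 14 or
    deep grey 16), mirroring one presented table each.
    """
    base = summaries[summaries["timepoint"] == "baseline"].set_index("subject_id")
    all_records = []
    for disease in ("RRMS", "NMOSD"):
        sub = base[base["group"] == disease]
        ids = [s for s in sub.index if s in volumes.table.index]
        vt = volumes.table.loc[ids]
        sub = sub.loc[ids]
        for metric, cols in (("fn", ("fn_short", "fn_middle", "fn_long")),
                             ("fa", ("fa_short", "fa_middle", "fa_long"))):
            for feats in (GLOBAL_VOLUME_FEATURES, DEEP_GM_VOLUME_FEATURES):
                family = []
                for cls_col in cols:
                    for f in feats:
                        rec = correlate(
                            sub[cls_col], vt[f], method=method,
                            x_name=cls_col, y_name=f,
                        )
                        family.append(rec)
                        all_records.append((disease, metric, rec))
                adjust_correlation_family(family)
    return _correlation_frame(all_records)


def correlate_network(
    summaries: pd.DataFrame, network: pd.DataFrame, method: str = "auto"
) -> pd.DataFrame:
    """FN/FA classes vs the four topology metrics, per disease and network."""
    base = summaries[summaries["timepoint"] == "baseline"].set_index("subject_id")
    all_records = []
    for net_kind, net_sub in network.groupby("network"):
        net_sub = net_sub.set_index("subject_id")
        for disease in ("RRMS", "NMOSD"):
            sub = base[base["group"] == disease]
            ids = [s for s in sub.index if s in net_sub.index]
            for metric, cols in (("fn", ("fn_short", "fn_middle", "fn_long")),
                                 ("fa", ("fa_short", "fa_middle", "fa_long"))):
                family = []
                for cls_col in cols:
                    for nm in NET_METRIC_COLUMNS:
                        rec = correlate(
                            sub.loc[ids, cls_col], net_sub.loc[ids, nm],
                            method=method, x_name=cls_col,
                            y_name=f"{net_kind}_{nm}",
                        )
                        family.append(rec)
                        all_records.append((disease, metric, rec))
                adjust_correlation_family(family)
    return _correlation_frame(all_records)


def correlate_clinical(summaries: pd.DataFrame, method: str = "auto") -> pd.DataFrame:
    """Lesion volume / EDSS / duration vs the six class outcomes, per disease."""
    base = summaries[summaries["timepoint"] == "baseline"]
    clinical = ("t2_lesion_volume", "edss", "disease_duration")
    all_records = []
    for disease in ("RRMS", "NMOSD"):
        sub = base[base["group"] == disease]
        family = []
        for var in clinical:
            v = sub[var].to_numpy(dtype=float)
            if np.isfinite(v).sum() < 3:
                continue
            for cls_col in ("fn_short", "fn_middle", "fn_long",
                            "fa_short", "fa_middle", "fa_long"):
                rec = correlate(sub[cls_col], v, method=method,
                                x_name=cls_col, y_name=var)
                family.append(rec)
                all_records.append((disease, "clinical", rec))
        adjust_correlation_family(family)
    return _correlation_frame(all_records)


def classify_patients(
    summaries: pd.DataFrame, k: int = 5, seed: int = 0
) -> CvRocResult:
    """RRMS-vs-NMOSD CV-LDA on the six stratified features."""
    base = summaries[
        (summaries["timepoint"] == "baseline")
        & summaries["group"].isin(["RRMS", "NMOSD"])
    ]
    feats = base.loc[:, ["fn_short", "fn_middle", "fn_long",
                         "fa_short", "fa_middle", "fa_long"]]
    return cv_lda_roc(feats, base["group"].to_numpy(), k=k, seed=seed)


def run_cross_sectional(config: RunConfig, cohort: Cohort | None = None) -> ResultBundle:
    """Execute every cross-sectional stage and assemble the result bundle."""
    t0 = time.time()
    if cohort is None:
        cohort = load_cohort(config)
    boundaries, summaries = compute_summaries(cohort, config.basis, config.fa_weighting)
    network = compute_network_table(cohort, config) if config.with_network_metrics else None

    comp_strat, gc_strat = compare_groups(summaries)
    comp_total, gc_total = compare_groups(summaries, outcomes=("fn_total",))
    comparisons = comp_strat + comp_total
    gc_df = pd.concat([gc_strat, gc_total], ignore_index=True)
    if cohort.volumes is not None:
        vol_df = correlate_volumes(summaries, cohort.volumes)
    else:
        vol_df = pd.DataFrame()
    net_df = (
        correlate_network(summaries, network)
        if network is not None and len(network)
        else pd.DataFrame()
    )
    clin_df = correlate_clinical(summaries)
    roc = classify_patients(summaries, k=config.roc_k, seed=config.seed)

    sidecar = {
        "seed": config.seed,
        "config": _config_dict(config),
        "config_hash": config_hash(config),
        "boundaries": asdict(boundaries),
        "n_subjects": len(cohort.manifest),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_s": round(time.time() - t0, 3),
    }
    bundle = ResultBundle(
        boundaries=boundaries, summaries=summaries, network=network,
        group_comparisons=gc_df, volume_correlations=vol_df,
        network_correlations=net_df, clinical_correlations=clin_df,
        roc=roc, comparisons=comparisons, sidecar=sidecar,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def run_longitudinal(
    config: RunConfig, cohort: Cohort | None = None
) -> tuple[pd.DataFrame, LengthBoundaries]:
    """Paired baseline-vs-follow-up tests per patient group per outcome.

    One FDR family covers the whole longitudinal outcome set (2 groups x
    7 outcomes). Boundaries are the frozen baseline-HC trisection.
    """
    if cohort is None:
        cohort = load_cohort(config)
    boundaries, summaries = compute_summaries(cohort, config.basis, config.fa_weighting)
    fu = summaries[summaries["timepoint"] == "followup"].set_index("subject_id")
    if fu.empty:
        raise ValidationError("no complete baseline/follow-up pairs in cohort")
    base = summaries[summaries["timepoint"] == "baseline"].set_index("subject_id")

    results: list[tuple[str, PairedComparison]] = []
    for grp in ("RRMS", "NMOSD"):
        ids = [s for s in fu.index if s in base.index and fu.loc[s, "group"] == grp]
        if not ids:
            continue
        for outcome in CLASS_OUTCOMES:
            pc = paired_compare(
                base.loc[ids, outcome], fu.loc[ids, outcome], outcome=outcome
            )
            results.append((grp, pc))
    if not results:
        raise ValidationError("no complete baseline/follow-up pairs in cohort")
    adj = fdr_bh([pc.p for _, pc in results])
    for (_, pc), q in zip(results, adj):
        pc.p_fdr = float(q)
    df = pd.DataFrame(
        [
            dict(group=g, outcome=pc.outcome, n_pairs=pc.n_pairs,
                 mean_difference=pc.mean_difference, t_stat=pc.t_stat,
                 p=pc.p, p_fdr=pc.p_fdr)
            for g, pc in results
        ]
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "longitudinal.csv", index=False)
        tio.write_sidecar(
            out / "longitudinal_sidecar.json",
            seed=config.seed, config=_config_dict(config),
            config_hash=config_hash(config), boundaries=asdict(boundaries),
            n_tests=len(df), timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
    return df, boundaries


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
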