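"""Synthetic connectome cohort generator.

Generates healthy-control (HC), RRMS-like and NMOSD-like subjects as full
(length, FN, FA) connectome triplets plus morphometry tables and a cohort
manifest, with the statistical structure the analysis pipeline assumes:

* node coordinates fixed on a sphere give every region pair a Euclidean
  base length, so the length trisection is nontrivial and stable;
* edge existence probability and expected streamline count both decay with
  distance, which reproduces the empirical class ordering of total
  streamline count (middle > short > long);
* per-edge FA rises with length tercile (long > middle > short);
* group effects are multiplicative on FN (counts) and additive on FA
  (bounded): the RRMS-like pattern raises short-range FN while lowering
  middle/long FN and lowers FA in all classes; the NMOSD-like pattern
  leaves FN untouched and lowers FA mildly;
* morphometric volumes load on each subject's standardized long-minus-short
  FN contrast, giving negative volume correlations with short-range FN and
  positive with long-range FN;
* a follow-up timepoint re-noises each subject around the same latent
  state, with optional per-class drift (default none: a longitudinal null).

All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    ALL_VOLUME_FEATURES,
    CohortManifest,
    ConnectomeTriplet,
    SubjectRecord,
    ValidationError,
    VolumeTable,
)

#: typical adult volume scales (mm^3) for the 30 canonical features
_BASE_VOLUMES = {
    "left_cerebellar_cortex": 53_000.0,
    "right_cerebellar_cortex": 54_000.0,
    "left_cerebellar_white_matter": 14_500.0,
    "right_cerebellar_white_matter": 14_000.0,
    "left_cerebral_cortex": 240_000.0,
    "right_cerebral_cortex": 241_000.0,
    "left_cerebral_white_matter": 230_000.0,
    "right_cerebral_white_matter": 231_000.0,
    "brain_stem": 21_000.0,
    "total_cortex": 481_000.0,
    "total_cerebral_white_matter": 461_000.0,
    "total_deep_grey_matter": 60_000.0,
    "total_grey_matter": 650_000.0,
    "total_intracranial_volume": 1_500_000.0,
    "left_thalamus": 7_500.0,
    "right_thalamus": 7_400.0,
    "left_caudate": 3_700.0,
    "right_caudate": 3_800.0,
    "left_putamen": 5_300.0,
    "right_putamen": 5_200.0,
    "left_pallidum": 1_800.0,
    "right_pallidum": 1_750.0,
    "left_amygdala": 1_600.0,
    "right_amygdala": 1_650.0,
    "left_accumbens": 600.0,
    "right_accumbens": 580.0,
    "left_ventral_diencephalon": 4_000.0,
    "right_ventral_diencephalon": 3_950.0,
    "left_hippocampus": 4_200.0,
    "right_hippocampus": 4_300.0,
}


@dataclass
class SyntheticCohortConfig:
    """Study conditions for the generated cohort.

    Cohort sizes default to the modeled study margins (56 HC, 51 RRMS,
    42 NMOSD at baseline; 25 RRMS and 20 NMOSD followed up). Group effects
    default to the qualitative disease patterns the analysis is built to
    detect; HC effects are identities by construction.
    """

    n_hc: int = 56
    n_rrms: int = 51
    n_nmosd: int = 42
    n_nodes: int = 148
    seed: int = 0

    # geometry: nodes on a sphere; edge probability decays with distance
    sphere_radius_mm: float = 70.0
    edge_prob_scale: float = 0.9
    edge_prob_decay_mm: float = 150.0

    # streamline counts: expected count at distance 0 and its length decay,
    # negative-binomial overdispersion, per-subject global scale jitter
    hc_fn_scale: float = 50.0
    fn_length_decay_mm: float = 70.0
    fn_dispersion: float = 20.0
    subject_fn_sigma: float = 0.05       # shared (head-size-like) FN scale
    class_fn_sigma: float = 0.10         # independent per-class FN scale
    length_jitter_sd: float = 0.02

    # FA per length tercile (short, middle, long)
    hc_fa_mean: tuple[float, float, float] = (0.38, 0.45, 0.52)
    hc_fa_sd: float = 0.03
    subject_fa_sigma: float = 0.015
    fa_noise_sd: float = 0.02

    # group effects per length class (short, middle, long)
    rrms_fn_scale: tuple[float, float, float] = (1.15, 0.80, 0.70)
    rrms_fa_shift: tuple[float, float, float] = (-0.06, -0.06, -0.06)
    nmosd_fn_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nmosd_fa_shift: tuple[float, float, float] = (-0.03, -0.03, -0.03)

    # morphometry loads on the standardized (fn_long - fn_short) contrast
    volume_coupling: float = 0.08
    volume_noise_sd: float = 0.06

    # longitudinal arm (patients only); identity drift encodes a null
    n_followup_rrms: int = 25
    n_followup_nmosd: int = 20
    followup_fn_drift: tuple[float, float, float] = (1.0, 1.0, 1.0)
    followup_fa_drift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    # demographics approximating the study margins
    age_mean: float = 39.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (18.0, 60.0)
    female_frac: dict = field(
        default_factory=lambda: {"HC": 31 / 56, "RRMS": 32 / 51, "NMOSD": 39 / 42}
    )

    with_functional: bool = False
    functional_timepoints: int = 120

    def validate(self) -> "SyntheticCohortConfig":
        for name, n in (("n_hc", self.n_hc), ("n_rrms", self.n_rrms), ("n_nmosd", self.n_nmosd)):
            if n < 2:
                raise ValidationError(f"{name} must be >= 2, got {n}")
        if self.n_nodes < 4:
            raise ValidationError("n_nodes must be >= 4")
        for shifts in (self.rrms_fa_shift, self.nmosd_fa_shift, self.followup_fa_drift):
            for mu, dv in zip(self.hc_fa_mean, shifts):
                if not (0.0 < mu + dv < 1.0):
                    raise ValidationError(
                        f"FA mean {mu} with shift {dv} leaves (0, 1)"
                    )
        if self.n_followup_rrms > self.n_rrms or self.n_followup_nmosd > self.n_nmosd:
            raise ValidationError("follow-up counts exceed baseline counts")
        return self

    def fn_scale(self, group: str) -> np.ndarray:
        return np.asarray(
            {"HC": (1.0, 1.0, 1.0), "RRMS": self.rrms_fn_scale, "NMOSD": self.nmosd_fn_scale}[group]
        )

    def fa_shift(self, group: str) -> np.ndarray:
        return np.asarray(
            {"HC": (0.0, 0.0, 0.0), "RRMS": self.rrms_fa_shift, "NMOSD": self.nmosd_fa_shift}[group]
        )


@dataclass
class _Geometry:
    coords: np.ndarray        # n_nodes x 3
    iu: tuple[np.ndarray, np.ndarray]
    base_length: np.ndarray   # per upper-triangle pair, mm
    edge_class: np.ndarray    # generator-truth tercile (0/1/2) per pair
    p_exist: np.ndarray
    fn_mean: np.ndarray       # HC expected count per pair
    fa_base: np.ndarray       # HC edge-level FA mean per pair


@dataclass
class _SubjectState:
    fn_factor: float                 # shared across classes
    class_factors: tuple[float, float, float]
    fa_offset: float


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    triplets: list[ConnectomeTriplet]
    volumes: VolumeTable
    manifest: CohortManifest
    functional: dict[str, np.ndarray] | None = None
    followup_triplets: list[ConnectomeTriplet] = field(default_factory=list)
    geometry: _Geometry | None = None
    subject_state: dict[str, _SubjectState] = field(default_factory=dict)

    def triplet_for(self, subject_id: str, timepoint: str = "baseline") -> ConnectomeTriplet:
        pool = self.triplets if timepoint == "baseline" else self.followup_triplets
        for t in pool:
            if t.subject_id == subject_id:
                return t
        raise KeyError((subject_id, timepoint))


def _make_geometry(cfg: SyntheticCohortConfig, rng: np.random.Generator) -> _Geometry:
    v = rng.standard_normal((cfg.n_nodes, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    coords = v * cfg.sphere_radius_mm
    iu = np.triu_indices(cfg.n_nodes, 1)
    d = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
    lo, hi = d.min(), d.max()
    edges = [lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3]
    edge_class = np.digitize(d, edges)
    p = np.clip(cfg.edge_prob_scale * np.exp(-d / cfg.edge_prob_decay_mm), 0, 1)
    fn_mean = cfg.hc_fn_scale * np.exp(-d / cfg.fn_length_decay_mm)
    fa_base = np.clip(
        np.asarray(cfg.hc_fa_mean)[edge_class] + rng.normal(0, cfg.hc_fa_sd, d.size),
        0.05,
        0.95,
    )
    return _Geometry(coords, iu, d, edge_class, p, fn_mean, fa_base)


def _subject_triplet(
    cfg: SyntheticCohortConfig,
    geom: _Geometry,
    rng: np.random.Generator,
    subject_id: str,
    group: str,
    state: _SubjectState,
    labels: tuple[str, ...],
    fn_drift: np.ndarray | None = None,
    fa_drift: np.ndarray | None = None,
) -> ConnectomeTriplet:
    n_pairs = geom.base_length.size
    cls = geom.edge_class
    mu = (
        geom.fn_mean
        * cfg.fn_scale(group)[cls]
        * state.fn_factor
        * np.asarray(state.class_factors)[cls]
    )
    if fn_drift is not None:
        mu = mu * fn_drift[cls]
    exist = rng.random(n_pairs) < geom.p_exist
    # negative-binomial counts via the gamma-Poisson mixture
    lam = rng.gamma(cfg.fn_dispersion, mu / cfg.fn_dispersion)
    fn = rng.poisson(lam)
    fn = np.where(exist, fn, 0)
    exist = fn > 0

    length = geom.base_length * np.exp(rng.normal(0, cfg.length_jitter_sd, n_pairs))
    fa = (
        geom.fa_base
        + cfg.fa_shift(group)[cls]
        + state.fa_offset
        + rng.normal(0, cfg.fa_noise_sd, n_pairs)
    )
    if fa_drift is not None:
        fa = fa + fa_drift[cls]
    fa = np.clip(fa, 0.01, 0.99)
    length = np.where(exist, length, 0.0)
    fa = np.where(exist, fa, 0.0)

    n = cfg.n_nodes
    mats = {}
    for name, vec, dtype in (("length", length, float), ("fn", fn, float), ("fa", fa, float)):
        m = np.zeros((n, n), dtype=dtype)
        m[geom.iu] = vec
        mats[name] = m + m.T
    return ConnectomeTriplet(
        subject_id=subject_id,
        node_labels=labels,
        length=mats["length"],
        fn=mats["fn"],
        fa=mats["fa"],
    )


def _fn_contrasts(
    triplets: list[ConnectomeTriplet], geom: _Geometry, groups: np.ndarray
) -> np.ndarray:
    """Standardized long-minus-short FN contrast per subject.

    Long and short totals are z-scored within each group before
    differencing, so the contrast reflects each subject's long-vs-short
    balance rather than a global (head-size-like) streamline-count scale or
    the group-level disease effect.
    """
    shorts = np.array(
        [t.fn[geom.iu][geom.edge_class == 0].sum() for t in triplets], dtype=float
    )
    longs = np.array(
        [t.fn[geom.iu][geom.edge_class == 2].sum() for t in triplets], dtype=float
    )
    c = np.empty(len(triplets))
    for g in np.unique(groups):
        m = groups == g
        zs = (shorts[m] - shorts[m].mean()) / shorts[m].std()
        zl = (longs[m] - longs[m].mean()) / longs[m].std()
        c[m] = zl - zs
    return (c - c.mean()) / c.std()


def _functional_matrix(cfg: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    t = cfg.functional_timepoints
    shared = rng.standard_normal((3, t))
    loadings = rng.normal(0, 0.5, (cfg.n_nodes, 3))
    ts = loadings @ shared + rng.standard_normal((cfg.n_nodes, t))
    C = np.corrcoef(ts)
    np.fill_diagonal(C, 0.0)
    return C


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate the baseline cohort: triplets, volume table and manifest."""
    cfg = config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    geom = _make_geometry(cfg, rng)
    labels = tuple(f"region_{i:03d}" for i in range(cfg.n_nodes))

    plan = (
        [("HC", i) for i in range(cfg.n_hc)]
        + [("RRMS", i) for i in range(cfg.n_rrms)]
        + [("NMOSD", i) for i in range(cfg.n_nmosd)]
    )
    triplets: list[ConnectomeTriplet] = []
    records: list[SubjectRecord] = []
    states: dict[str, _SubjectState] = {}
    functional: dict[str, np.ndarray] = {}
    for group, i in plan:
        sid = f"{group.lower()}_{i:03d}"
        state = _SubjectState(
            fn_factor=float(np.exp(rng.normal(0, cfg.subject_fn_sigma))),
            class_factors=tuple(np.exp(rng.normal(0, cfg.class_fn_sigma, 3))),
            fa_offset=float(rng.normal(0, cfg.subject_fa_sigma)),
        )
        states[sid] = state
        triplets.append(_subject_triplet(cfg, geom, rng, sid, group, state, labels))
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), *cfg.age_range))
        sex = "F" if rng.random() < cfg.female_frac[group] else "M"
        if group == "HC":
            dur = edss = t2lv = None
        else:
            dur = float(np.round(rng.gamma(2.0, 2.5), 1))
            edss = float(np.clip(np.round(rng.normal(2.5, 1.2) * 2) / 2, 0.0, 10.0))
            lv_mu, lv_sd = (18.0, 13.0) if group == "RRMS" else (3.7, 4.0)
            t2lv = float(np.round(max(abs(rng.normal(lv_mu, lv_sd)), 0.1), 2))
        records.append(
            SubjectRecord(
                subject_id=sid, group=group, age=age, sex=sex,
                timepoint="baseline", disease_duration=dur, edss=edss,
                t2_lesion_volume=t2lv,
            )
        )
        if cfg.with_functional:
            functional[sid] = _functional_matrix(cfg, rng)

    # morphometry: volumes load on the standardized long-minus-short contrast
    z = _fn_contrasts(triplets, geom, np.array([g for g, _ in plan]))
    rows = {}
    for t, zi in zip(triplets, z):
        noise = rng.normal(0, cfg.volume_noise_sd, len(ALL_VOLUME_FEATURES))
        factors = np.clip(1.0 + cfg.volume_coupling * zi + noise, 0.4, None)
        rows[t.subject_id] = {
            f: _BASE_VOLUMES[f] * fac for f, fac in zip(ALL_VOLUME_FEATURES, factors)
        }
    vt = VolumeTable(pd.DataFrame.from_dict(rows, orient="index"))

    return SyntheticCohort(
        config=cfg,
        triplets=triplets,
        volumes=vt,
        manifest=CohortManifest(records),
        functional=functional if cfg.with_functional else None,
        geometry=geom,
        subject_state=states,
    )


def generate_followup(
    cohort: SyntheticCohort, config: SyntheticCohortConfig | None = None
) -> SyntheticCohort:
    """Add a re-noised second timepoint for the followed patient subset.

    Each followed subject keeps its latent state (global FN factor, FA
    offset) and group effects; measurement noise is redrawn and the
    configured per-class drift is applied, so the default identity drift is
    an exact longitudinal null.
    """
    cfg = (config or cohort.config).validate()
    if cohort.geometry is None:
        raise ValidationError("cohort lacks generator state; regenerate it")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    fn_drift = np.asarray(cfg.followup_fn_drift, dtype=float)
    fa_drift = np.asarray(cfg.followup_fa_drift, dtype=float)

    chosen = [r for r in cohort.manifest if r.group == "RRMS"][: cfg.n_followup_rrms]
    chosen += [r for r in cohort.manifest if r.group == "NMOSD"][: cfg.n_followup_nmosd]
    labels = cohort.triplets[0].node_labels
    fu_triplets: list[ConnectomeTriplet] = []
    fu_records: list[SubjectRecord] = []
    for r in chosen:
        fu_triplets.append(
            _subject_triplet(
                cfg, cohort.geometry, rng, r.subject_id, r.group,
                cohort.subject_state[r.subject_id], labels,
                fn_drift=fn_drift, fa_drift=fa_drift,
            )
        )
        fu_records.append(
            replace(
                r,
                timepoint="followup",
                edss=None if r.edss is None else float(
                    np.clip(np.round((r.edss + abs(rng.normal(0.4, 0.3))) * 2) / 2, 0, 10)
                ),
                t2_lesion_volume=None if r.t2_lesion_volume is None else float(
                    np.round(r.t2_lesion_volume * (1 + abs(rng.normal(0.1, 0.1))), 2)
                ),
            )
        )
    manifest = CohortManifest(list(cohort.manifest.records) + fu_records)
    return SyntheticCohort(
        config=cfg,
        triplets=cohort.triplets,
        volumes=cohort.volumes,
        manifest=manifest,
        functional=cohort.functional,
        followup_triplets=fu_triplets,
        geometry=cohort.geometry,
        subject_state=cohort.subject_state,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write the cohort to disk in the exact formats the readers accept."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    from . import io as tio

    out = Path(out_dir)
    mat_dir = out / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for r in cohort.manifest:
        trip = cohort.triplet_for(r.subject_id, r.timepoint)
        sid = trip.subject_id if r.timepoint == "baseline" else f"{trip.subject_id}_fu"
        paths = tio.write_triplet(
            ConnectomeTriplet(sid, trip.node_labels, trip.length, trip.fn, trip.fa),
            mat_dir,
        )
        rec = replace(
            r,
            length_path=str(paths["length"].relative_to(out)),
            fn_path=str(paths["fn"].relative_to(out)),
            fa_path=str(paths["fa"].relative_to(out)),
        )
        if cohort.functional and r.subject_id in cohort.functional and r.timepoint == "baseline":
            fpath = mat_dir / f"{sid}_functional.csv"
            tio.write_matrix(fpath, cohort.functional[r.subject_id])
            rec = replace(rec, functional_path=str(fpath.relative_to(out)))
        records.append(rec)
    tio.write_manifest(CohortManifest(records), out / "manifest.csv")
    tio.write_volume_table(cohort.volumes, out / "volumes.csv")
    tio.write_labels(out / "node_labels.txt", cohort.triplets[0].node_labels)
    cfg = asdict(cohort.config)
    (out / "cohort_config.json").write_text(json.dumps(cfg, indent=2) + "\n")
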