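"""Core data containers for length-stratified connectome analysis.

A subject's structural connectome arrives as a *triplet* of square
region-by-region matrices over a shared cortical parcellation (148 regions
by default, matching a Destrieux-style atlas): mean streamline length (mm),
streamline count (fiber number, FN) and mean fractional anisotropy (FA).
Cohort-level metadata travels in a manifest table; FreeSurfer-style
morphometry arrives as a 30-feature volume table (14 global features plus
16 deep grey-matter regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_N_NODES = 148

GROUPS = ("HC", "RRMS", "NMOSD")
SEXES = ("F", "M")
TIMEPOINTS = ("baseline", "followup")

#: canonical global morphometry features (mm^3)
GLOBAL_VOLUME_FEATURES = (
    "left_cerebellar_cortex",
    "right_cerebellar_cortex",
    "left_cerebellar_white_matter",
    "right_cerebellar_white_matter",
    "left_cerebral_cortex",
    "right_cerebral_cortex",
    "left_cerebral_white_matter",
    "right_cerebral_white_matter",
    "brain_stem",
    "total_cortex",
    "total_cerebral_white_matter",
    "total_deep_grey_matter",
    "total_grey_matter",
    "total_intracranial_volume",
)

#: canonical deep grey-matter regions (mm^3)
DEEP_GM_VOLUME_FEATURES = (
    "left_thalamus",
    "right_thalamus",
    "left_caudate",
    "right_caudate",
    "left_putamen",
    "right_putamen",
    "left_pallidum",
    "right_pallidum",
    "left_amygdala",
    "right_amygdala",
    "left_accumbens",
    "right_accumbens",
    "left_ventral_diencephalon",
    "right_ventral_diencephalon",
    "left_hippocampus",
    "right_hippocampus",
)

ALL_VOLUME_FEATURES = GLOBAL_VOLUME_FEATURES + DEEP_GM_VOLUME_FEATURES

#: common FreeSurfer aseg/stats spellings accepted by the volume reader
VOLUME_COLUMN_ALIASES = {
    "Left-Cerebellum-Cortex": "left_cerebellar_cortex",
    "Right-Cerebellum-Cortex": "right_cerebellar_cortex",
    "Left-Cerebellum-White-Matter": "left_cerebellar_white_matter",
    "Right-Cerebellum-White-Matter": "right_cerebellar_white_matter",
    "lhCortexVol": "left_cerebral_cortex",
    "rhCortexVol": "right_cerebral_cortex",
    "lhCerebralWhiteMatterVol": "left_cerebral_white_matter",
    "rhCerebralWhiteMatterVol": "right_cerebral_white_matter",
    "Brain-Stem": "brain_stem",
    "CortexVol": "total_cortex",
    "CerebralWhiteMatterVol": "total_cerebral_white_matter",
    "SubCortGrayVol": "total_deep_grey_matter",
    "TotalGrayVol": "total_grey_matter",
    "EstimatedTotalIntraCranialVol": "total_intracranial_volume",
    "eTIV": "total_intracranial_volume",
    "Left-Thalamus-Proper": "left_thalamus",
    "Right-Thalamus-Proper": "right_thalamus",
    "Left-Thalamus": "left_thalamus",
    "Right-Thalamus": "right_thalamus",
    "Left-Caudate": "left_caudate",
    "Right-Caudate": "right_caudate",
    "Left-Putamen": "left_putamen",
    "Right-Putamen": "right_putamen",
    "Left-Pallidum": "left_pallidum",
    "Right-Pallidum": "right_pallidum",
    "Left-Amygdala": "left_amygdala",
    "Right-Amygdala": "right_amygdala",
    "Left-Accumbens-area": "left_accumbens",
    "Right-Accumbens-area": "right_accumbens",
    "Left-VentralDC": "left_ventral_diencephalon",
    "Right-VentralDC": "right_ventral_diencephalon",
    "Left-Hippocampus": "left_hippocampus",
    "Right-Hippocampus": "right_hippocampus",
}


class ValidationError(ValueError):
    """A container failed its structural or range invariants."""


class StructuralError(ValueError):
    """Input files disagree on shape or labeling."""


def _check_square_symmetric(m: np.ndarray, name: str, rtol: float = 1e-6) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise StructuralError(f"{name}: expected a square matrix, got shape {m.shape}")
    scale = max(np.abs(m).max(), 1.0)
    if not np.allclose(m, m.T, rtol=0, atol=rtol * scale):
        raise ValidationError(f"{name}: asymmetry exceeds relative tolerance {rtol:g}")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class ConnectomeTriplet:
    """Per-subject (length, FN, FA) connectome matrices over shared nodes.

    Invariants: all matrices symmetric with zero diagonal; an edge exists
    iff fn > 0, and then length > 0 and fa in (0, 1]; absent edges are 0
    in all three matrices.
    """

    subject_id: str
    node_labels: tuple[str, ...]
    length: np.ndarray  # mm
    fn: np.ndarray      # streamline counts
    fa: np.ndarray      # unitless, [0, 1]

    def __post_init__(self) -> None:
        self.node_labels = tuple(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def validate(self, coerce: bool = True) -> "ConnectomeTriplet":
        """Check invariants; with ``coerce`` stray values on fn=0 edges are
        zeroed with a warning instead of raising."""
        n = self.n_nodes
        if len(set(self.node_labels)) != n:
            raise ValidationError(f"{self.subject_id}: node labels are not unique")
        self.length = _check_square_symmetric(self.length, f"{self.subject_id}/length")
        self.fn = _check_square_symmetric(self.fn, f"{self.subject_id}/fn")
        self.fa = _check_square_symmetric(self.fa, f"{self.subject_id}/fa")
        for name, m in (("length", self.length), ("fn", self.fn), ("fa", self.fa)):
            if m.shape[0] != n:
                raise StructuralError(
                    f"{self.subject_id}/{name}: matrix is {m.shape[0]}x{m.shape[1]} "
                    f"but {n} node labels were given"
                )
        if (self.fn < 0).any():
            raise ValidationError(f"{self.subject_id}/fn: negative streamline counts")
        bad_fa = (self.fa < -1e-9) | (self.fa > 1 + 1e-9)
        if bad_fa.any():
            idx = np.argwhere(np.triu(bad_fa, 1))
            raise ValidationError(
                f"{self.subject_id}/fa: entries outside [0, 1] at edges "
                f"{[tuple(map(int, e)) for e in idx[:10]]}"
            )
        self.fa = np.clip(self.fa, 0.0, 1.0)

        absent = self.fn == 0
        stray = absent & ((self.length != 0) | (self.fa != 0))
        if stray.any():
            if not coerce:
                raise ValidationError(
                    f"{self.subject_id}: {int(np.triu(stray, 1).sum())} fn=0 edges "
                    "carry nonzero length/FA"
                )
            warnings.warn(
                f"{self.subject_id}: zeroing length/FA on "
                f"{int(np.triu(stray, 1).sum())} fn=0 edges",
                stacklevel=2,
            )
            self.length = np.where(absent, 0.0, self.length)
            self.fa = np.where(absent, 0.0, self.fa)
        present = self.fn > 0
        incomplete = present & ((self.length <= 0) | (self.fa <= 0))
        if incomplete.any():
            raise ValidationError(
                f"{self.subject_id}: {int(np.triu(incomplete, 1).sum())} fn>0 edges "
                "have nonpositive length or FA"
            )
        return self

    @property
    def existing(self) -> np.ndarray:
        """Boolean adjacency of existing edges (fn > 0)."""
        return self.fn > 0


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    timepoint: str = "baseline"
    disease_duration: float | None = None
    edss: float | None = None
    t2_lesion_volume: float | None = None
    length_path: str | None = None
    fn_path: str | None = None
    fa_path: str | None = None
    functional_path: str | None = None


@dataclass
class CohortManifest:
    """Typed cohort roster; one row per subject x timepoint."""

    records: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen = set()
        baselines = set()
        for r in self.records:
            if r.group not in GROUPS:
                raise ValidationError(f"unknown group {r.group!r} for {r.subject_id}")
            if r.sex not in SEXES:
                raise ValidationError(f"unknown sex {r.sex!r} for {r.subject_id}")
            if r.timepoint not in TIMEPOINTS:
                raise ValidationError(f"unknown timepoint {r.timepoint!r} for {r.subject_id}")
            key = (r.subject_id, r.timepoint)
            if key in seen:
                raise ValidationError(f"duplicate subject x timepoint {key}")
            seen.add(key)
            if r.timepoint == "baseline":
                baselines.add(r.subject_id)
            if r.group == "HC" and any(
                v is not None for v in (r.disease_duration, r.edss, r.t2_lesion_volume)
            ):
                raise ValidationError(
                    f"HC subject {r.subject_id} carries clinical fields"
                )
        orphans = sorted(
            r.subject_id
            for r in self.records
            if r.timepoint == "followup" and r.subject_id not in baselines
        )
        if orphans:
            raise ValidationError(f"follow-up rows without baseline: {orphans}")

    def subset(self, group: str | None = None, timepoint: str | None = None) -> "CohortManifest":
        recs = [
            r
            for r in self.records
            if (group is None or r.group == group)
            and (timepoint is None or r.timepoint == timepoint)
        ]
        return CohortManifest(recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class VolumeTable:
    """Per-subject morphometry, 30 canonical features in mm^3."""

    table: pd.DataFrame  # index: subject_id, columns: ALL_VOLUME_FEATURES

    def __post_init__(self) -> None:
        missing = [c for c in ALL_VOLUME_FEATURES if c not in self.table.columns]
        if missing:
            raise ValidationError(f"volume table missing canonical columns: {missing}")
        self.table = self.table.loc[:, list(ALL_VOLUME_FEATURES)].astype(float)
        if (self.table.values <= 0).any():
            bad = self.table.index[(self.table.values <= 0).any(axis=1)].tolist()
            raise ValidationError(f"nonpositive volumes for subjects: {bad}")
        tiv = self.table["total_intracranial_volume"].values[:, None]
        if (self.table.values > tiv + 1e-9).any():
            bad = self.table.index[
                (self.table.values > tiv + 1e-9).any(axis=1)
            ].tolist()
            raise ValidationError(
                f"feature exceeds total intracranial volume for subjects: {bad}"
            )

    def for_subjects(self, subject_ids: Sequence[str]) -> "VolumeTable":
        missing = [s for s in subject_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"volume table missing subjects: {missing}")
        return VolumeTable(self.table.loc[list(subject_ids)].copy())
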