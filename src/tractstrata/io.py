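"""Reading and writing connectome matrices, manifests and volume tables.

File dialects are deliberately plain: matrices are delimited text
(comma or whitespace, auto-detected), manifests and volume tables are CSV
with a header, node labels are one region name per line. Every writer has
a matching reader and round-trips values at full repr precision.
"""

from __future__ import annotations

import json
import math
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ALL_VOLUME_FEATURES,
    GROUPS,
    SEXES,
    TIMEPOINTS,
    VOLUME_COLUMN_ALIASES,
    CohortManifest,
    ConnectomeTriplet,
    StructuralError,
    SubjectRecord,
    ValidationError,
    VolumeTable,
)

_MANIFEST_REQUIRED = ("subject_id", "group", "age", "sex")
_MANIFEST_OPTIONAL = (
    "timepoint",
    "disease_duration",
    "edss",
    "t2_lesion_volume",
    "length_path",
    "fn_path",
    "fa_path",
    "functional_path",
)


def read_matrix(path: str | Path) -> np.ndarray:
    """Load a delimited square numeric matrix, auto-detecting the delimiter."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0] if path.stat().st_size else ""
    delim = "," if "," in first else None  # None = any whitespace
    try:
        m = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise StructuralError(f"{path}: could not parse numeric matrix ({exc})") from exc
    if m.shape[0] != m.shape[1]:
        raise StructuralError(f"{path}: matrix is {m.shape[0]}x{m.shape[1]}, not square")
    return m


def write_matrix(path: str | Path, m: np.ndarray) -> None:
    np.savetxt(path, np.asarray(m, dtype=float), delimiter=",", fmt="%.17g")


def read_labels(path: str | Path) -> tuple[str, ...]:
    labels = tuple(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{path}: duplicate node labels")
    return labels


def write_labels(path: str | Path, labels: Sequence[str]) -> None:
    Path(path).write_text("\n".join(labels) + "\n")


def read_triplet(
    length_path: str | Path,
    fn_path: str | Path,
    fa_path: str | Path,
    labels_path: str | Path,
    subject_id: str | None = None,
) -> ConnectomeTriplet:
    """Read and validate one subject's (length, FN, FA) matrix triplet.

    Matrices are symmetrized as (M + M')/2 when asymmetry is within a
    relative tolerance of 1e-6 and the diagonal is forced to zero; larger
    asymmetry, shape mismatches or out-of-range FA raise.
    """
    labels = read_labels(labels_path)
    mats = {}
    for name, p in (("length", length_path), ("fn", fn_path), ("fa", fa_path)):
        m = read_matrix(p)
        if m.shape[0] != len(labels):
            raise StructuralError(
                f"{p}: {name} matrix is {m.shape[0]}x{m.shape[1]} but labels file "
                f"{labels_path} has {len(labels)} regions"
            )
        mats[name] = m
    sid = subject_id or Path(fn_path).stem
    trip = ConnectomeTriplet(
        subject_id=sid,
        node_labels=labels,
        length=mats["length"],
        fn=mats["fn"],
        fa=mats["fa"],
    )
    return trip.validate()


def write_triplet(triplet: ConnectomeTriplet, out_dir: str | Path) -> dict[str, Path]:
    """Write one triplet as three CSV matrices plus the labels file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = triplet.subject_id
    paths = {
        "length": out_dir / f"{sid}_length.csv",
        "fn": out_dir / f"{sid}_fn.csv",
        "fa": out_dir / f"{sid}_fa.csv",
        "labels": out_dir / "node_labels.txt",
    }
    write_matrix(paths["length"], triplet.length)
    write_matrix(paths["fn"], triplet.fn)
    write_matrix(paths["fa"], triplet.fa)
    write_labels(paths["labels"], triplet.node_labels)
    return paths


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, str) and not v.strip()):
        return None
    f = float(v)
    return None if math.isnan(f) else f


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV into typed, validated records.

    Group, sex and timepoint values are normalized case-insensitively;
    optional clinical fields become explicit ``None`` (never zero).
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise StructuralError(f"{path}: manifest missing columns {missing}")
    norm = {g.lower(): g for g in GROUPS}
    norm.update({s.lower(): s for s in SEXES})
    norm.update({t.lower(): t for t in TIMEPOINTS})
    norm.update({"follow-up": "followup", "follow_up": "followup"})
    records = []
    for _, row in df.iterrows():
        group = norm.get(str(row["group"]).strip().lower())
        if group not in GROUPS:
            raise ValidationError(f"{path}: unknown group label {row['group']!r}")
        sex = norm.get(str(row["sex"]).strip().lower())
        if sex not in SEXES:
            raise ValidationError(f"{path}: unknown sex label {row['sex']!r}")
        tp_raw = _opt_str(row.get("timepoint")) or "baseline"
        tp = norm.get(tp_raw.lower())
        if tp not in TIMEPOINTS:
            raise ValidationError(f"{path}: unknown timepoint {tp_raw!r}")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]).strip(),
                group=group,
                age=float(row["age"]),
                sex=sex,
                timepoint=tp,
                disease_duration=_opt_float(row.get("disease_duration")),
                edss=_opt_float(row.get("edss")),
                t2_lesion_volume=_opt_float(row.get("t2_lesion_volume")),
                length_path=_opt_str(row.get("length_path")),
                fn_path=_opt_str(row.get("fn_path")),
                fa_path=_opt_str(row.get("fa_path")),
                functional_path=_opt_str(row.get("functional_path")),
            )
        )
    return CohortManifest(records)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    rows = [asdict(r) for r in manifest.records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_volume_table(
    path: str | Path, manifest: CohortManifest | None = None
) -> VolumeTable:
    """Read a morphometry CSV into the 30-feature canonical volume table.

    Common FreeSurfer column spellings (e.g. ``Left-Thalamus-Proper``) are
    mapped via a documented alias table; the result is restricted to
    subjects present in ``manifest`` when one is given.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise StructuralError(f"{path}: volume table missing subject_id column")
    df = df.rename(columns=VOLUME_COLUMN_ALIASES)
    missing = [c for c in ALL_VOLUME_FEATURES if c not in df.columns]
    if missing:
        raise StructuralError(f"{path}: volume table missing columns {missing}")
    df = df.set_index("subject_id")
    df.index = df.index.astype(str)
    vt = VolumeTable(df)
    if manifest is not None:
        ids = sorted({r.subject_id for r in manifest})
        keep = [s for s in ids if s in vt.table.index]
        vt = VolumeTable(vt.table.loc[keep])
    return vt


def write_volume_table(vt: VolumeTable, path: str | Path) -> None:
    vt.table.rename_axis("subject_id").to_csv(path)


def write_sidecar(path: str | Path, **payload) -> None:
    """Write the JSON run-metadata sidecar (versions, seed, config, counts)."""
    meta = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    meta.update(payload)
    Path(path).write_text(json.dumps(meta, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
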