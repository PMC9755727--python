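"""Fiber-length trisection and per-class FN / FA summaries.

The healthy-control (HC) cohort defines the length scale: edge-wise mean
streamline lengths are averaged over HC subjects carrying the edge, and the
range of that group-average matrix is split into three equal-width bins.
Every connection of every subject is then labeled short-, middle- or
long-range against those fixed cut points, and per-subject macrostructure
(summed streamline count, FN) and microstructure (edge-wise mean FA) are
aggregated per class.

Interval convention: [l_min, b1), [b1, b2), [b2, l_max], with subject
lengths outside the HC range clamped into the extreme classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ConnectomeTriplet, ValidationError

# edge-class codes
ABSENT, SHORT, MIDDLE, LONG = -1, 0, 1, 2
CLASS_NAMES = {SHORT: "short", MIDDLE: "middle", LONG: "long"}


@dataclass(frozen=True)
class LengthBoundaries:
    """Equal-width trisection cut points of the HC length range (mm)."""

    l_min: float
    b1: float
    b2: float
    l_max: float

    def __post_init__(self) -> None:
        if not (self.l_min < self.b1 < self.b2 < self.l_max):
            raise ValidationError(f"boundaries not strictly increasing: {self}")
        widths = np.diff([self.l_min, self.b1, self.b2, self.l_max])
        if not np.allclose(widths, widths[0], rtol=1e-12, atol=0):
            raise ValidationError(f"bins are not equal-width: {self}")


@dataclass
class EdgeClassMask:
    """Symmetric label matrix; upper-triangle entries in {short, middle, long, absent}."""

    labels: np.ndarray  # int matrix of ABSENT/SHORT/MIDDLE/LONG codes
    basis: str          # "subject" or "hc_average"

    def counts(self) -> dict[str, int]:
        iu = np.triu_indices(self.labels.shape[0], 1)
        lab = self.labels[iu]
        return {name: int((lab == code).sum()) for code, name in CLASS_NAMES.items()}


@dataclass
class StratifiedSummary:
    """Per-subject FN and mean FA per length class (the unit of analysis)."""

    subject_id: str
    fn_short: float
    fn_middle: float
    fn_long: float
    fn_total: float
    fa_short: float | None
    fa_middle: float | None
    fa_long: float | None
    edge_count: dict[str, int]

    def as_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "fn_short": self.fn_short,
            "fn_middle": self.fn_middle,
            "fn_long": self.fn_long,
            "fn_total": self.fn_total,
            "fa_short": self.fa_short,
            "fa_middle": self.fa_middle,
            "fa_long": self.fa_long,
        }
        d.update({f"n_edges_{k}": v for k, v in self.edge_count.items()})
        return d


def hc_average_length(hc_triplets: list[ConnectomeTriplet]) -> np.ndarray:
    """Group-average length matrix over the HC cohort.

    Entry (i, j) is the mean of length(i, j) over the HC subjects in which
    the edge exists (fn > 0); 0 where no HC subject has the edge.
    """
    if not hc_triplets:
        raise ValidationError("need at least one HC triplet")
    labels = hc_triplets[0].node_labels
    for t in hc_triplets[1:]:
        if t.node_labels != labels:
            raise ValidationError(
                f"node order mismatch between {hc_triplets[0].subject_id} and {t.subject_id}"
            )
    lengths = np.stack([t.length for t in hc_triplets])
    present = np.stack([t.existing for t in hc_triplets])
    count = present.sum(axis=0)
    total = (lengths * present).sum(axis=0)
    with np.errstate(invalid="ignore"):
        avg = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    np.fill_diagonal(avg, 0.0)
    return avg


def compute_boundaries(avg_length: np.ndarray) -> LengthBoundaries:
    """Trisect the positive support of the HC-average length matrix.

    l_min / l_max are the minimum and maximum over positive entries and the
    interior cut points split [l_min, l_max] into three equal-width bins.
    """
    pos = avg_length[avg_length > 0]
    if pos.size == 0:
        raise ValidationError("average length matrix has no positive entries")
    l_min, l_max = float(pos.min()), float(pos.max())
    if l_min == l_max:
        raise ValidationError(
            f"degenerate length range: all positive entries equal {l_min}"
        )
    b1 = l_min + (l_max - l_min) / 3.0
    b2 = l_min + 2.0 * (l_max - l_min) / 3.0
    return LengthBoundaries(l_min=l_min, b1=b1, b2=b2, l_max=l_max)


def classify_edges(
    triplet: ConnectomeTriplet,
    boundaries: LengthBoundaries,
    basis: str = "subject",
    hc_avg_length: np.ndarray | None = None,
) -> EdgeClassMask:
    """Label every edge short / middle / long against the HC cut points.

    basis="subject" (default): each edge is classified by the subject's own
    mean streamline length; edges with fn = 0 are absent. Lengths below
    l_min clamp to short, above l_max to long.
    basis="hc_average": the edge inherits the class of the HC-average
    length; edges absent from the HC average are absent, so all subjects
    share one mask.
    """
    if basis == "subject":
        L = triplet.length
        absent = ~triplet.existing
    elif basis == "hc_average":
        if hc_avg_length is None:
            raise ValidationError("basis='hc_average' requires hc_avg_length")
        L = hc_avg_length
        absent = hc_avg_length == 0
    else:
        raise ValidationError(f"unknown classification basis {basis!r}")

    labels = np.full(L.shape, MIDDLE, dtype=np.int8)
    labels[L < boundaries.b1] = SHORT
    labels[L >= boundaries.b2] = LONG
    labels[absent] = ABSENT
    np.fill_diagonal(labels, ABSENT)
    return EdgeClassMask(labels=labels, basis=basis)


def summarize(triplet: ConnectomeTriplet, mask: EdgeClassMask) -> StratifiedSummary:
    """Aggregate FN (sum) and FA (unweighted edge mean) per length class.

    fn_total is the sum over existing, class-labeled edges, so
    fn_short + fn_middle + fn_long == fn_total exactly; a class with no
    existing edges reports FA as None. FN-weighted FA is available via
    ``summarize_weighted``.
    """
    if triplet.fn.shape != mask.labels.shape:
        raise ValidationError("triplet and mask have different shapes")
    iu = np.triu_indices(triplet.n_nodes, 1)
    lab = mask.labels[iu]
    fn = triplet.fn[iu]
    fa = triplet.fa[iu]
    existing = fn > 0

    fn_c, fa_c, n_c = {}, {}, {}
    for code, name in CLASS_NAMES.items():
        in_class = (lab == code) & existing
        fn_c[name] = float(fn[in_class].sum())
        n_c[name] = int(in_class.sum())
        fa_c[name] = float(fa[in_class].mean()) if n_c[name] else None
    return StratifiedSummary(
        subject_id=triplet.subject_id,
        fn_short=fn_c["short"],
        fn_middle=fn_c["middle"],
        fn_long=fn_c["long"],
        fn_total=fn_c["short"] + fn_c["middle"] + fn_c["long"],
        fa_short=fa_c["short"],
        fa_middle=fa_c["middle"],
        fa_long=fa_c["long"],
        edge_count=n_c,
    )


def summarize_weighted(triplet: ConnectomeTriplet, mask: EdgeClassMask) -> StratifiedSummary:
    """Variant of :func:`summarize` with FN-weighted per-class FA means."""
    base = summarize(triplet, mask)
    iu = np.triu_indices(triplet.n_nodes, 1)
    lab = mask.labels[iu]
    fn = triplet.fn[iu]
    fa = triplet.fa[iu]
    existing = fn > 0
    for code, name in CLASS_NAMES.items():
        in_class = (lab == code) & existing
        w = fn[in_class]
        val = float(np.average(fa[in_class], weights=w)) if w.sum() > 0 else None
        setattr(base, f"fa_{name}", val)
    return base
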