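"""Segment algebra and binding-site prediction metrics.

A binding site is a :class:`SegmentSet`: sorted, non-overlapping, merged
half-open residue intervals ``[a, b)``.  The two headline metrics are

* the overlap score — summed pairwise intersections between predicted and
  ground-truth segments, normalized by total ground-truth length
  (equivalently, for merged sets, ``|predicted residues ∩ truth residues| /
  |truth residues|``); and
* the false-positive rate — the fraction of predicted length lying in
  segments that intersect *no* ground-truth segment.  The indicator is per
  whole predicted segment; a per-residue variant is provided separately.

The module also builds the coverage-matched random baseline, the docking
grid box (cube centered on the mean binding-site atom coordinate, default
side 50 Å) and the aggregate evaluation report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SegmentSet",
    "overlap_score",
    "false_positive_rate",
    "false_positive_rate_residues",
    "random_baseline",
    "GridBox",
    "grid_box",
    "barycenter_distance",
    "extract_site_coordinates",
    "EvalReport",
    "evaluate",
    "load_segments_json",
    "save_segments_json",
]


@dataclass(frozen=True)
class SegmentSet:
    """Sorted, non-overlapping, merged half-open integer intervals.

    The strict invariants (``a < b``, ``b_i <= a_{i+1}`` with no touching
    segments) are what make the interval-arithmetic metric formulas agree
    with residue-set counting; use :meth:`from_intervals` to normalize
    arbitrary interval collections first.
    """

    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in segs:
            if a >= b:
                raise ValueError(f"empty or inverted segment [{a}, {b})")
            if a < 0:
                raise ValueError(f"negative residue index in [{a}, {b})")
        for (_, b1), (a2, _) in zip(segs, segs[1:]):
            if b1 > a2:
                raise ValueError("segments must be sorted and non-overlapping")
            if b1 == a2:
                raise ValueError("touching segments must be merged")

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[int, int]]) -> "SegmentSet":
        """Sort, merge touching/overlapping intervals, and validate."""
        ivs = sorted((int(a), int(b)) for a, b in intervals)
        merged: list[list[int]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return cls(tuple((a, b) for a, b in merged))

    @property
    def total_length(self) -> int:
        return sum(b - a for a, b in self.segments)

    def coverage(self, sequence_length: int) -> float:
        if sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        return self.total_length / sequence_length

    def residues(self) -> set[int]:
        """Explicit residue-index set (the brute-force representation)."""
        out: set[int] = set()
        for a, b in self.segments:
            out.update(range(a, b))
        return out

    def __len__(self) -> int:
        return len(self.segments)

    def __bool__(self) -> bool:
        return bool(self.segments)


def overlap_score(predicted: SegmentSet, truth: SegmentSet) -> float:
    """Summed pairwise interval intersections / total ground-truth length."""
    denom = truth.total_length
    if denom == 0:
        raise ValueError("overlap score undefined for empty ground truth")
    num = 0
    for ap, bp in predicted.segments:
        for at, bt in truth.segments:
            num += max(0, min(bp, bt) - max(ap, at))
    return num / denom


def false_positive_rate(predicted: SegmentSet, truth: SegmentSet) -> float:
    """Fraction of predicted length in segments disjoint from all truth.

    The indicator is evaluated per whole predicted segment: a segment that
    touches any ground-truth segment contributes nothing.
    """
    denom = predicted.total_length
    if denom == 0:
        raise ValueError("false positive rate undefined for empty prediction")
    num = 0
    for ap, bp in predicted.segments:
        intersects = any(
            min(bp, bt) - max(ap, at) > 0 for at, bt in truth.segments
        )
        if not intersects:
            num += bp - ap
    return num / denom


def false_positive_rate_residues(predicted: SegmentSet, truth: SegmentSet) -> float:
    """Per-residue variant: fraction of predicted residues outside the truth."""
    pred = predicted.residues()
    if not pred:
        raise ValueError("false positive rate undefined for empty prediction")
    return len(pred - truth.residues()) / len(pred)


def random_baseline(
    sequence_length: int,
    coverage: float,
    n_segments: int,
    seed: int,
) -> SegmentSet:
    """Coverage- and count-matched random placement.

    Places ``n_segments`` non-overlapping segments totalling
    ``round(coverage * sequence_length)`` residues, with sizes split as
    evenly as possible and positions drawn uniformly over all valid
    arrangements (uniform gap composition).
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    total = int(np.floor(coverage * sequence_length + 0.5))
    if total < n_segments:
        raise ValueError(
            f"cannot place {n_segments} non-empty segments totalling {total} residues"
        )
    if total > sequence_length:
        raise ValueError("coverage exceeds sequence length")
    rng = np.random.default_rng(seed)
    base, extra = divmod(total, n_segments)
    sizes = [base + (1 if i < extra else 0) for i in range(n_segments)]
    free = sequence_length - total
    # Internal gaps must be >= 1 to keep the n segments separated; reserve
    # that slack when feasible, then draw the remaining free residues as a
    # uniform gap composition via the stars-and-bars bijection.
    reserve = n_segments - 1 if free >= n_segments - 1 else 0
    spare = free - reserve
    bars = np.sort(rng.choice(spare + n_segments, size=n_segments, replace=False))
    gaps = np.diff(np.concatenate([[-1], bars, [spare + n_segments]])) - 1
    segments = []
    pos = 0
    for i, (gap, size) in enumerate(zip(gaps[:-1], sizes)):
        pos += int(gap) + (1 if reserve and i > 0 else 0)
        segments.append((pos, pos + size))
        pos += size
    # Without reserved gaps segments may touch; merging preserves total length.
    return SegmentSet.from_intervals(segments)


# --------------------------------------------------------------------------
# Docking grid boxes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GridBox:
    """Axis-aligned cube for docking, centered on the binding site."""

    center: tuple[float, float, float]
    side: float = 50.0

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("grid box side must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


def grid_box(points: Sequence[Sequence[float]], side: float = 50.0) -> GridBox:
    """Cube centered on the arithmetic mean of binding-site atom coordinates."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("grid box requires at least one point")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array of coordinates")
    return GridBox(center=tuple(pts.mean(axis=0)), side=side)


def barycenter_distance(box1: GridBox, box2: GridBox) -> float:
    """Euclidean distance between grid-box centers, in Å."""
    return float(np.linalg.norm(np.subtract(box1.center, box2.center)))


def extract_site_coordinates(
    pdb_path: str | Path,
    chain_id: str,
    residue_ids: Iterable[int],
    model_index: int = 0,
) -> np.ndarray:
    """Atom coordinates of the given residues from a PDB file.

    Residue numbers are taken verbatim from the file (author numbering).
    Returns an (N, 3) array over all atoms of the selected residues.
    """
    from Bio.PDB import PDBParser

    wanted = set(int(i) for i in residue_ids)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = list(structure)[model_index]
    coords = [
        atom.coord
        for residue in model[chain_id]
        if residue.id[1] in wanted
        for atom in residue
    ]
    if not coords:
        raise ValueError(
            f"no atoms found for chain {chain_id!r} residues {sorted(wanted)}"
        )
    return np.asarray(coords, dtype=float)


# --------------------------------------------------------------------------
# Report aggregation
# --------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-example and aggregate overlap score / FPR.

    ``mean_*`` are arithmetic means of per-example values; ``pooled_*``
    aggregate numerators and denominators over examples before dividing.
    Examples with an empty prediction (no FPR defined) or empty truth (no
    OS defined) are excluded from the respective statistic and counted.
    """

    per_example: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_overlap_score: float = float("nan")
    mean_false_positive_rate: float = float("nan")
    pooled_overlap_score: float = float("nan")
    pooled_false_positive_rate: float = float("nan")
    mean_coverage: float = float("nan")
    n_examples: int = 0
    n_missing_prediction: int = 0
    n_missing_truth: int = 0
    config: dict | None = None

    def to_dict(self) -> dict:
        return {
            "mean_overlap_score": self.mean_overlap_score,
            "mean_false_positive_rate": self.mean_false_positive_rate,
            "pooled_overlap_score": self.pooled_overlap_score,
            "pooled_false_positive_rate": self.pooled_false_positive_rate,
            "mean_coverage": self.mean_coverage,
            "n_examples": self.n_examples,
            "n_missing_prediction": self.n_missing_prediction,
            "n_missing_truth": self.n_missing_truth,
            "config": self.config,
            "per_example": self.per_example,
        }


def evaluate(
    predictions: Mapping[str, SegmentSet],
    truths: Mapping[str, SegmentSet],
    sequence_lengths: Mapping[str, int] | None = None,
    config: dict | None = None,
) -> EvalReport:
    """Match predictions to ground truth by identifier and aggregate metrics."""
    missing_truth = sorted(set(predictions) - set(truths))
    missing_pred = sorted(set(truths) - set(predictions))
    if missing_truth or missing_pred:
        raise ValueError(
            "identifier mismatch; "
            f"predictions without truth: {missing_truth[:10]}, "
            f"truths without prediction: {missing_pred[:10]}"
        )
    report = EvalReport(config=config)
    os_vals, fpr_vals, cov_vals = [], [], []
    os_num = os_den = 0
    fpr_num = fpr_den = 0
    for key in sorted(predictions):
        pred, truth = predictions[key], truths[key]
        entry: dict[str, float] = {}
        if truth:
            entry["overlap_score"] = overlap_score(pred, truth)
            os_vals.append(entry["overlap_score"])
            for ap, bp in pred.segments:
                for at, bt in truth.segments:
                    os_num += max(0, min(bp, bt) - max(ap, at))
            os_den += truth.total_length
        else:
            report.n_missing_truth += 1
        if pred:
            entry["false_positive_rate"] = false_positive_rate(pred, truth)
            fpr_vals.append(entry["false_positive_rate"])
            for ap, bp in pred.segments:
                if not any(min(bp, bt) - max(ap, at) > 0 for at, bt in truth.segments):
                    fpr_num += bp - ap
            fpr_den += pred.total_length
        else:
            report.n_missing_prediction += 1
        if sequence_lengths is not None and pred and key in sequence_lengths:
            entry["coverage"] = pred.coverage(sequence_lengths[key])
            cov_vals.append(entry["coverage"])
        report.per_example[key] = entry
    report.n_examples = len(predictions)
    if os_vals:
        report.mean_overlap_score = float(np.mean(os_vals))
        report.pooled_overlap_score = os_num / os_den
    if fpr_vals:
        report.mean_false_positive_rate = float(np.mean(fpr_vals))
        report.pooled_false_positive_rate = fpr_num / fpr_den
    if cov_vals:
        report.mean_coverage = float(np.mean(cov_vals))
    return report


# --------------------------------------------------------------------------
# JSON schema: {id: [[start, end], ...]} with 0-based half-open segments
# --------------------------------------------------------------------------


def load_segments_json(path: str | Path) -> dict[str, SegmentSet]:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        key: SegmentSet.from_intervals([(a, b) for a, b in intervals])
        for key, intervals in raw.items()
    }


def save_segments_json(segments: Mapping[str, SegmentSet], path: str | Path) -> None:
    payload = {key: [list(seg) for seg in s.segments] for key, s in segments.items()}
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
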