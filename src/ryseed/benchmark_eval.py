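"""Binary-classification scoring of alignments against simulation truth.

Endogenous (e.g. mitochondrial) reads are the positives: a read mapped to
within the tolerance (default 50 bp, inclusive, circular distance on
circular references) of its true location is a true positive, any other
mapping is a false positive, and an unmapped endogenous read is a false
negative.  Contaminant reads are the negatives: unmapped contaminants are
true negatives and — in the labeling this harness reproduces — *mapped
contaminants are counted as false negatives*.  That labeling is
nonstandard (conventionally a mapped contaminant is a false positive) but
is kept as the default so the accompanying metric formulas reproduce
exactly; ``conventional_labels=True`` switches to the standard convention.

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), and F1 as the
harmonic mean of precision TP/(TP+FP) and recall TP/(TP+FN).  Undefined
denominators yield None, not 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Set, Tuple

import pandas as pd

__all__ = [
    "ConfusionCounts",
    "classify",
    "metrics",
    "compare_runs",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be nonnegative")


def _read_primaries(sam_path: str) -> Dict[str, Optional[Tuple[str, int]]]:
    """qname -> (reference name, 0-based pos) for mapped primaries, None if unmapped."""
    import pysam

    out: Dict[str, Optional[Tuple[str, int]]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.query_name in out:
                raise ValueError(f"duplicate primary record for {aln.query_name!r}")
            if aln.is_unmapped:
                out[aln.query_name] = None
            else:
                out[aln.query_name] = (aln.reference_name, aln.reference_start)
    return out


def _distance(a: int, b: int, length: Optional[int], circular: bool) -> int:
    d = abs(a - b)
    if circular and length:
        d = min(d, length - d)
    return d


def classify(sam_path: str, truth: pd.DataFrame, tolerance: int = 50,
             circular: Optional[Set[str]] = None,
             ref_lengths: Optional[Dict[str, int]] = None,
             conventional_labels: bool = False) -> ConfusionCounts:
    """Score primary alignments against the truth table.

    ``circular`` names references on which distance wraps; their lengths
    come from ``ref_lengths`` or the SAM header.  Alignment records whose
    read id is absent from the truth are rejected.
    """
    import pysam

    circular = circular or set()
    primaries = _read_primaries(sam_path)
    if ref_lengths is None:
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
            ref_lengths = dict(zip(fh.references, fh.lengths))
    truth_ids = set(truth["id"])
    stray = set(primaries) - truth_ids
    if stray:
        raise ValueError(f"alignment id(s) not in truth table: {sorted(stray)[:5]}")
    tp = fp = tn = fn = 0
    for rid, label, sid, start in zip(truth["id"], truth["class"],
                                      truth["seq_id"], truth["start"]):
        placement = primaries.get(rid)
        if label == "endogenous":
            if placement is None:
                fn += 1
            else:
                rname, pos = placement
                if rname == sid and _distance(
                    pos, int(start), ref_lengths.get(rname), rname in circular
                ) <= tolerance:
                    tp += 1
                else:
                    fp += 1
        else:
            if placement is None:
                tn += 1
            elif conventional_labels:
                fp += 1
            else:
                fn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(c: ConfusionCounts) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """(sensitivity, specificity, F1); None where a denominator is zero."""
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    prec = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    rec = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    if prec is None or rec is None or (prec + rec) == 0:
        f1 = None
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return sens, spec, f1


def _per_class_mapped(sam_path: str, truth: pd.DataFrame) -> Dict[str, str]:
    """'aligned/total' cells per read class, Table-style."""
    primaries = _read_primaries(sam_path)
    out = {}
    for label, sub in truth.groupby("class"):
        mapped = sum(1 for rid in sub["id"] if primaries.get(rid) is not None)
        out[str(label)] = f"{mapped}/{len(sub)}"
    return out


def compare_runs(sam_a: str, sam_b: str, truth: pd.DataFrame,
                 tolerance: int = 50, circular: Optional[Set[str]] = None,
                 conventional_labels: bool = False) -> dict:
    """Two-run report: per-run confusion counts, metrics, per-class
    aligned/total cells, and deltas (run A minus run B).

    Both runs must cover the same read universe as the truth table.
    """
    ids = set(truth["id"])
    for path in (sam_a, sam_b):
        seen = set(_read_primaries(path))
        if seen != ids:
            raise ValueError(f"{path}: read universe does not match truth table")
    report = {}
    counts = {}
    for tag, path in (("a", sam_a), ("b", sam_b)):
        c = classify(path, truth, tolerance, circular,
                     conventional_labels=conventional_labels)
        sens, spec, f1 = metrics(c)
        counts[tag] = c
        report[tag] = {
            "counts": c,
            "sensitivity": sens,
            "specificity": spec,
            "f1": f1,
            "mapped_by_class": _per_class_mapped(path, truth),
        }
    ca, cb = counts["a"], counts["b"]
    report["delta"] = {
        "TP": ca.TP - cb.TP,
        "FP": ca.FP - cb.FP,
        "TN": ca.TN - cb.TN,
        "FN": ca.FN - cb.FN,
    }
    return report
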