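"""Score pipeline predictions against simulator truth: precision/recall
with one-to-one truth matching, plus TAF / allele-copy-number accuracy
per planted zygosity class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

DEFAULT_MATCH_WINDOW = 10


@dataclass
class MatchResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    matches: list[tuple[int, int, int]]  # (truth index, call index, offset bp)
    window: int = DEFAULT_MATCH_WINDOW

    @property
    def precision(self) -> float | None:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else None

    @property
    def recall(self) -> float | None:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else None

    def to_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
            "window": self.window,
            "matches": self.matches,
        }


def _call_key(call) -> tuple[str, int, str]:
    return call.contig, call.start, call.family


def _truth_key(truth) -> tuple[str, int, str]:
    return truth.contig, truth.position, truth.family


def match_predictions(
    calls: Sequence,
    truths: Sequence,
    window: int = DEFAULT_MATCH_WINDOW,
    require_family: bool = True,
) -> MatchResult:
    """Greedy one-to-one matching by smallest position offset.

    A (call, truth) pair is eligible iff they share a contig, the
    position offset is <= ``window`` bp, and (when ``require_family``)
    the family agrees.  Pairs are consumed smallest offset first, so
    each call and each truth participates in at most one match.
    """
    pairs = []
    for ti, truth in enumerate(truths):
        t_contig, t_pos, t_family = _truth_key(truth)
        for ci, call in enumerate(calls):
            c_contig, c_pos, c_family = _call_key(call)
            if c_contig != t_contig:
                continue
            if require_family and c_family != t_family:
                continue
            offset = c_pos - t_pos
            if abs(offset) <= window:
                pairs.append((abs(offset), ti, ci, offset))
    pairs.sort()
    matched_t: set[int] = set()
    matched_c: set[int] = set()
    matches = []
    for _, ti, ci, offset in pairs:
        if ti in matched_t or ci in matched_c:
            continue
        matched_t.add(ti)
        matched_c.add(ci)
        matches.append((ti, ci, offset))
    tp = len(matches)
    return MatchResult(
        true_positives=tp,
        false_positives=len(calls) - tp,
        false_negatives=len(truths) - tp,
        matches=matches,
        window=window,
    )


def taf_accuracy(
    calls: Sequence,
    truths: Sequence,
    match: MatchResult,
) -> pd.DataFrame:
    """Per planted-carrier-count table of TAF and copy-number accuracy.

    Columns: number of matched insertions, mean estimated TAF, mean
    absolute TAF error vs k/ploidy, and the fraction whose predicted
    allele copy number equals the planted carrier count (exact under
    uniform copy number).  Unmatched calls/truths are excluded.
    """
    rows = []
    for ti, ci, _ in match.matches:
        truth = truths[ti]
        call = calls[ci]
        if call.taf is None:
            continue
        k = truth.true_allele_copy_number
        rows.append(
            {
                "carrier_count": k,
                "true_taf": truth.true_taf,
                "taf": call.taf,
                "abs_error": abs(call.taf - truth.true_taf),
                "cn_exact": int(call.allele_copy_number == k),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["n", "mean_taf", "mean_true_taf", "mae", "cn_exact_frac"]
        )
    df = pd.DataFrame(rows)
    out = df.groupby("carrier_count").agg(
        n=("taf", "size"),
        mean_taf=("taf", "mean"),
        mean_true_taf=("true_taf", "mean"),
        mae=("abs_error", "mean"),
        cn_exact_frac=("cn_exact", "mean"),
    )
    return out


def per_zygosity_recall(truths: Sequence, match: MatchResult) -> pd.DataFrame:
    """Recall broken down by planted carrier count."""
    matched = {ti for ti, _, _ in match.matches}
    rows = [
        {"carrier_count": t.true_allele_copy_number, "found": int(i in matched)}
        for i, t in enumerate(truths)
    ]
    df = pd.DataFrame(rows)
    return df.groupby("carrier_count").agg(n=("found", "size"), recall=("found", "mean"))
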