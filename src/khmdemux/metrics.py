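"""Evaluation metrics against ground-truth donor labels.

Two primary metrics: the Adjusted Rand Index (Hubert-Arabie, chance-
corrected pair agreement) between true donors and predicted clusters on
singlet cells, and the count of incorrectly merged clusters — predicted
clusters that absorb the cells of two or more true donors, detected by
mapping each donor to the predicted cluster holding the plurality of
its cells.  A secondary diagnostic counts split donors: donors whose
cells are weakly concentrated (< 60% by default) in their modal
cluster.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _contingency(truth_labels, pred_labels) -> np.ndarray:
    truth_labels = np.asarray(truth_labels)
    pred_labels = np.asarray(pred_labels)
    if truth_labels.shape != pred_labels.shape or truth_labels.ndim != 1:
        raise ValueError(
            f"label vectors must be equal-length 1-d; got {truth_labels.shape} "
            f"and {pred_labels.shape}"
        )
    _, ti = np.unique(truth_labels, return_inverse=True)
    _, pi = np.unique(pred_labels, return_inverse=True)
    C = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(C, (ti, pi), 1)
    return C


def adjusted_rand_index(truth_labels, pred_labels) -> float:
    """Hubert-Arabie ARI; 1 iff the partitions match up to relabeling.

    The degenerate case where expected and maximum index coincide (e.g.
    both partitions a single class) is reported as 1.0 with a warning.
    """
    C = _contingency(truth_labels, pred_labels)
    n = int(C.sum())
    if n < 2:
        raise ValueError("ARI needs at least two cells")

    def comb2(x):
        x = x.astype(float)
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(C).sum()
    a = comb2(C.sum(axis=1)).sum()
    b = comb2(C.sum(axis=0)).sum()
    n2 = n * (n - 1.0) / 2.0
    expected = a * b / n2
    maximum = 0.5 * (a + b)
    if maximum == expected:
        warnings.warn("degenerate partitions (expected == max index); ARI reported as 1.0")
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))


def _modal_map(C: np.ndarray) -> np.ndarray:
    # per true donor, the predicted cluster holding most of its cells;
    # ties resolve to the lowest cluster id (np.argmax takes the first max)
    return np.argmax(C, axis=1)


def incorrectly_merged_count(truth_labels, pred_labels) -> int:
    """Predicted clusters that are modal for two or more true donors."""
    C = _contingency(truth_labels, pred_labels)
    modal = _modal_map(C)
    hits = np.bincount(modal, minlength=C.shape[1])
    return int(np.sum(hits >= 2))


def one_to_one_donors(truth_labels, pred_labels) -> int:
    """Donors whose modal cluster is claimed by no other donor."""
    C = _contingency(truth_labels, pred_labels)
    modal = _modal_map(C)
    hits = np.bincount(modal, minlength=C.shape[1])
    return int(np.sum(hits[modal] == 1))


def split_donor_count(truth_labels, pred_labels, min_concentration: float = 0.6) -> int:
    """Donors with < ``min_concentration`` of cells in their modal cluster."""
    C = _contingency(truth_labels, pred_labels)
    modal = _modal_map(C)
    totals = C.sum(axis=1)
    frac = C[np.arange(C.shape[0]), modal] / np.maximum(totals, 1)
    return int(np.sum(frac < min_concentration))


def doublet_precision_recall(true_doublet, called_doublet) -> tuple[float, float]:
    """Precision and recall of doublet calls; NaN when undefined."""
    t = np.asarray(true_doublet, dtype=bool)
    c = np.asarray(called_doublet, dtype=bool)
    tp = int((t & c).sum())
    precision = tp / c.sum() if c.sum() else float("nan")
    recall = tp / t.sum() if t.sum() else float("nan")
    return float(precision), float(recall)


def evaluate_calls(
    calls_df: pd.DataFrame, truth_df: pd.DataFrame, all_true_singlets: bool = False
) -> dict:
    """Score a cell-calls table against a truth table (barcode-joined).

    By default ARI / merge metrics use cells that are true singlets AND
    called singlet; ``all_true_singlets`` scores every true singlet
    instead, treating its best cluster as the prediction.
    """
    merged = truth_df.merge(calls_df, on="barcode", how="inner", validate="one_to_one")
    if len(merged) != len(truth_df) or len(merged) != len(calls_df):
        missing = sorted(
            set(truth_df["barcode"]).symmetric_difference(calls_df["barcode"])
        )[:5]
        raise ValueError(f"barcode sets differ between calls and truth; e.g. {missing}")
    true_singlet = merged["is_doublet"] == 0
    called_singlet = merged["status"] == "singlet"
    scored = true_singlet if all_true_singlets else (true_singlet & called_singlet)
    sub = merged[scored]
    if all_true_singlets:
        # fall back to the best singlet cluster for non-singlet calls
        cluster_cols = [c for c in merged.columns if c.startswith("cluster")]
        pred = np.where(
            sub["status"] == "singlet",
            sub["assignment"].where(sub["status"] == "singlet", "0"),
            np.asarray(sub[cluster_cols]).argmax(axis=1).astype(str),
        )
    else:
        pred = sub["assignment"].to_numpy()
    t = sub["donor"].to_numpy()
    prec, rec = doublet_precision_recall(
        merged["is_doublet"] == 1, merged["status"] == "doublet"
    )
    return {
        "n_scored": int(len(sub)),
        "ari": adjusted_rand_index(t, pred),
        "incorrectly_merged": incorrectly_merged_count(t, pred),
        "split_donors": split_donor_count(t, pred),
        "one_to_one_donors": one_to_one_donors(t, pred),
        "doublet_precision": prec,
        "doublet_recall": rec,
    }
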