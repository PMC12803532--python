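"""Recovery metrics for synthetic-truth experiments (label matching, accuracy)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["match_groups", "map_accuracy"]


def match_groups(true_labels, predicted_labels):
    """Best bijective mapping predicted -> true label maximizing agreement.

    Uses the Hungarian algorithm on the confusion matrix.  Returns a dict
    mapping each predicted label to a true label (unmatched predictions map
    to None when there are more predicted than true categories).
    """
    t = pd.Series(np.asarray(true_labels)).astype(str)
    p = pd.Series(np.asarray(predicted_labels)).astype(str)
    confusion = pd.crosstab(p, t)
    rows, cols = linear_sum_assignment(-confusion.to_numpy())
    mapping = {confusion.index[r]: confusion.columns[c] for r, c in zip(rows, cols)}
    for lbl in confusion.index:
        mapping.setdefault(lbl, None)
    return mapping


def map_accuracy(true_labels, predicted_labels, per_group: bool = False):
    """MAP assignment accuracy vs. truth under the best label matching.

    With per_group=True returns (overall, {true_group: accuracy}).
    """
    t = pd.Series(np.asarray(true_labels)).astype(str).reset_index(drop=True)
    p = pd.Series(np.asarray(predicted_labels)).astype(str).reset_index(drop=True)
    mapping = match_groups(t, p)
    mapped = p.map(lambda x: mapping.get(x))
    correct = mapped == t
    overall = float(correct.mean())
    if not per_group:
        return overall
    by_group = {g: float(correct[t == g].mean()) for g in t.unique()}
    return overall, by_group
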