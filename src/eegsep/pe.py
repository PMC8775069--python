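"""Permutation entropy of inputs and CNN feature maps, plus class-separability
statistics.

Permutation entropy (PE) is the Shannon entropy (base 2) of the distribution
of ordinal patterns of ``order`` consecutive, ``delay``-spaced values:
``PE = -sum p(pi) * log2 p(pi)`` over the ``order!`` patterns ``pi``.  Ties
within a window are broken by order of appearance (stable ranking), which
makes PE well defined on rectified feature maps containing runs of zeros.
PE is bounded by ``log2(order!)``, reaches 0 for monotone series, and is
invariant under strictly increasing transformations.

The interpretability procedure computes PE along the temporal axis of each
feature-map slice at the input, Conv1 and Conv2 stages, averages over filters
(and sub-bands at the input) and then over a subject's epochs, yielding one
scalar per (subject, layer, EEG channel).  Per-channel class differences are
assessed with the Wilcoxon rank-sum test; classifier accuracy tables are
compared with the Friedman test followed by the Nemenyi post hoc procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, factorial
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sstats

from .cnn import FEATURE_LAYERS, ConvNet


@dataclass(frozen=True)
class PEParams:
    """Ordinal-pattern parameters (log base fixed at 2)."""

    order: int = 3
    delay: int = 1
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.delay < 1:
            raise ValueError("delay must be >= 1")

    @property
    def max_entropy_bits(self) -> float:
        return float(np.log2(factorial(self.order)))


@dataclass(frozen=True)
class StatTestResult:
    """Outcome of one hypothesis test (pairwise matrix for Nemenyi)."""

    name: str
    statistic: float
    p_value: float
    pairwise: Optional[pd.DataFrame] = None
    details: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Permutation entropy
# ---------------------------------------------------------------------------

def ordinal_pattern_codes(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    """Integer pattern codes of all windows of a (..., T) array.

    Codes are ``sum_j rank_position[j] * order**j`` of the stable argsort of
    each window; distinct patterns map to distinct codes in
    ``[0, order**order)``.
    """
    x = np.asarray(x)
    span = (order - 1) * delay + 1
    if x.shape[-1] < span:
        raise ValueError(
            f"series of length {x.shape[-1]} too short for order {order}, "
            f"delay {delay}"
        )
    win = sliding_window_view(x, span, axis=-1)[..., ::delay]
    perm = np.argsort(win, axis=-1, kind="stable")
    weights = order ** np.arange(order)
    return perm @ weights


def _entropy_from_codes(codes: np.ndarray, order: int,
                        chunk_elems: int = 40_000_000) -> np.ndarray:
    """Shannon entropy (bits) per row of an (M, K) code array."""
    M, K = codes.shape
    nbins = order ** order
    out = np.empty(M)
    rows_per_chunk = max(1, chunk_elems // max(nbins, K))
    for s in range(0, M, rows_per_chunk):
        c = codes[s : s + rows_per_chunk]
        m = c.shape[0]
        flat = c + (np.arange(m) * nbins)[:, None]
        counts = np.bincount(flat.ravel(), minlength=m * nbins)
        counts = counts.reshape(m, nbins)
        p = counts / K
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        out[s : s + m] = h
    return out


def permutation_entropy_batch(x: np.ndarray,
                              params: PEParams = PEParams()) -> np.ndarray:
    """PE (bits) along the last axis of an arbitrary-shape array."""
    x = np.asarray(x)
    codes = ordinal_pattern_codes(x, params.order, params.delay)
    lead = codes.shape[:-1]
    h = _entropy_from_codes(codes.reshape(-1, codes.shape[-1]), params.order)
    h = h.reshape(lead)
    if params.normalize:
        h = h / params.max_entropy_bits
    return h


def permutation_entropy(x: np.ndarray, params: PEParams = PEParams()) -> float:
    """PE (bits) of a single 1-D series."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    return float(permutation_entropy_batch(x[None, :], params)[0])


# ---------------------------------------------------------------------------
# Per-layer PE table
# ---------------------------------------------------------------------------

def layer_pe_table(
    model: ConvNet,
    subjects: Sequence[Tuple[str, str, np.ndarray]],
    params: PEParams = PEParams(),
    layers: Sequence[str] = FEATURE_LAYERS,
    max_epochs_per_subject: Optional[int] = None,
    batch_size: int = 64,
) -> pd.DataFrame:
    """One PE scalar per (subject, layer, EEG channel).

    ``subjects`` holds (subject_id, class_label, values) with ``values`` the
    per-epoch sub-band tensor (epochs, channels, samples, bands).  For every
    layer the activation array is reduced by computing PE along the temporal
    axis of each (epoch, channel, filter) series, averaging over filters
    (sub-bands at the input) and then over epochs.

    Returns a DataFrame with columns subject_id, class, layer, channel
    (1-based), pe.
    """
    for layer in layers:
        if layer not in FEATURE_LAYERS:
            raise ValueError(f"unknown layer {layer!r}; use {FEATURE_LAYERS}")
    rows: List[dict] = []
    span = (params.order - 1) * params.delay + 1
    for sid, cls, values in subjects:
        values = np.asarray(values)
        if max_epochs_per_subject is not None:
            values = values[:max_epochs_per_subject]
        for layer in layers:
            per_channel_sum = None
            n_done = 0
            for s in range(0, values.shape[0], batch_size):
                maps = model.feature_maps(values[s : s + batch_size], layer)
                # (b, channels, T, filters) -> PE along T
                if maps.shape[2] < span:
                    raise ValueError(
                        f"layer {layer}: temporal length {maps.shape[2]} "
                        f"shorter than pattern span {span}"
                    )
                series = np.moveaxis(maps, 2, 3)  # (b, ch, filters, T)
                h = permutation_entropy_batch(series, params)
                ch_mean = h.mean(axis=2).sum(axis=0)  # sum over epochs
                per_channel_sum = (ch_mean if per_channel_sum is None
                                   else per_channel_sum + ch_mean)
                n_done += maps.shape[0]
            pe = per_channel_sum / n_done
            for ci, val in enumerate(pe):
                rows.append({
                    "subject_id": sid, "class": cls, "layer": layer,
                    "channel": ci + 1, "pe": float(val),
                })
    return pd.DataFrame(rows)


def channel_separability(pe_table: pd.DataFrame,
                         bonferroni: bool = False) -> pd.DataFrame:
    """Per-(layer, channel) Wilcoxon rank-sum p-values between classes.

    ``bonferroni`` multiplies p-values by the number of channels per layer
    (off by default; per-channel reporting is the primary mode).
    """
    classes = sorted(pe_table["class"].unique())
    if len(classes) != 2:
        raise ValueError("pe table must contain exactly two classes")
    rows = []
    for (layer, channel), grp in pe_table.groupby(["layer", "channel"],
                                                  sort=True):
        a = grp.loc[grp["class"] == classes[0], "pe"].to_numpy()
        b = grp.loc[grp["class"] == classes[1], "pe"].to_numpy()
        res = wilcoxon_rank_sum(a, b)
        rows.append({
            "layer": layer, "channel": channel,
            f"mean_{classes[0]}": a.mean(), f"mean_{classes[1]}": b.mean(),
            "p_value": res.p_value,
        })
    out = pd.DataFrame(rows)
    if bonferroni:
        n = out.groupby("layer")["channel"].transform("count")
        out["p_value"] = np.minimum(1.0, out["p_value"] * n)
    return out


def significant_channel_counts(separability: pd.DataFrame,
                               alpha: float = 0.05) -> Dict[str, int]:
    """Number of channels with class difference at level alpha, per layer."""
    return {
        layer: int((grp["p_value"] < alpha).sum())
        for layer, grp in separability.groupby("layer")
    }


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      exact_limit: int = 200_000) -> StatTestResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the rank sum of the first sample.  When the number of
    label assignments C(n1+n2, n1) does not exceed ``exact_limit`` the
    p-value is computed from the exhaustive permutation distribution of the
    rank sum (handles ties exactly); otherwise the normal approximation with
    tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    if comb(n1 + n2, n1) <= exact_limit:
        dev = abs(w - mu) - 1e-9
        count = sum(
            1 for idx in combinations(range(n1 + n2), n1)
            if abs(ranks[list(idx)].sum() - mu) >= dev
        )
        p = count / comb(n1 + n2, n1)
        method = "exact"
        z = np.nan
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1.0))
        var = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
        if var <= 0:  # all observations identical
            return StatTestResult("wilcoxon_rank_sum", w, 1.0,
                                  details={"method": "degenerate"})
        z = (w - mu) / np.sqrt(var)
        p = min(1.0, 2.0 * sstats.norm.sf(abs(z)))
        method = "normal"
    return StatTestResult("wilcoxon_rank_sum", w, p,
                          details={"method": method, "z": float(z),
                                   "n1": n1, "n2": n2})


def friedman_nemenyi(accuracy_matrix: np.ndarray,
                     classifier_names: Optional[Sequence[str]] = None
                     ) -> StatTestResult:
    """Friedman chi-square over within-block ranks + Nemenyi pairwise matrix.

    ``accuracy_matrix`` is blocks x classifiers.  Ties receive average
    ranks; the tie-corrected statistic is used (identical rows are tolerated
    and an all-tied table yields statistic 0, p = 1).  The Nemenyi matrix is
    always attached; it is meaningful when the Friedman test is significant.
    """
    mat = np.asarray(accuracy_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a 2-D blocks x classifiers matrix, >= 2 columns")
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 blocks")
    n, k = mat.shape
    if classifier_names is None:
        classifier_names = [f"C{j + 1}" for j in range(k)]
    ranks = np.apply_along_axis(sstats.rankdata, 1, mat)
    col_sums = ranks.sum(axis=0)
    # tie-corrected Friedman statistic (Conover's T1); reduces to the
    # classic 12/(nk(k+1)) sum Rj^2 - 3n(k+1) form without ties
    A = float(np.sum(ranks ** 2))
    C = n * k * (k + 1) ** 2 / 4.0
    if A <= C + 1e-12:
        stat, p = 0.0, 1.0
    else:
        stat = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2)) \
            / (A - C)
        p = float(sstats.chi2.sf(stat, k - 1))

    mean_ranks = col_sums / n
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    pw = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            pij = float(sstats.studentized_range.sf(q, k, np.inf))
            pw[i, j] = pw[j, i] = min(1.0, pij)
    pairwise = pd.DataFrame(pw, index=list(classifier_names),
                            columns=list(classifier_names))
    return StatTestResult("friedman", stat, p, pairwise=pairwise,
                          details={"mean_ranks": dict(zip(classifier_names,
                                                          mean_ranks))})
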