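"""Simulation-study harness: hot/cold classification, metrics, ROC, sweeps.

Reproduces the validation experiments: simulate hotspot scenarios, walk the
true ARG of each sample, classify haplotypes hot/cold from the strength
profile, score sensitivity/specificity/accuracy against the simulator's
truth labels, and run the unimodality-filter experiment (two-allele versus
all-hot/all-cold samples) summarized as a ROC over dip scores.

Profiles computed from a sample are *symmetrized*: haplotypes with
identical sequences are exchangeable given the data, so they receive the
mean strength of their identical-sequence group.  Without this, profile
spread reflects pedigree detail no haplotype-based method could resolve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popsim import HaplotypeSample, Scenario, simulate_sample
from .rw_engine import RecombProfile, walk_profile
from .unimodality_filter import DIP_THRESHOLD, dip_pvalue, dip_statistic

logger = logging.getLogger("argwalker")

__all__ = [
    "SampleMetrics",
    "RocCurve",
    "sample_profile",
    "symmetrize_profile",
    "classify_hot_cold",
    "confusion_metrics",
    "roc_auc",
    "run_experiment",
    "dip_experiment",
]


@dataclass(frozen=True)
class SampleMetrics:
    """Per-sample confusion-matrix summary; 'hot' is the positive class."""

    tag: str
    sensitivity: float  # TP / (TP + FN); NaN if no true hots
    specificity: float  # TN / (TN + FP); NaN if no true colds
    accuracy: float
    n_hot: int
    n_cold: int


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def symmetrize_profile(profile: RecombProfile, sample: HaplotypeSample) -> RecombProfile:
    """Average strengths within identical-haplotype-sequence groups.

    Haplotypes whose sequences are identical cannot be distinguished by any
    method whose input is the haplotype matrix, so their strengths are
    replaced by the group mean (probabilities are re-derived; the total is
    unchanged, so V_p still sums to 1).
    """
    idx = {h: i for i, h in enumerate(sample.hap_ids)}
    groups: dict[bytes, list[str]] = {}
    for h in profile.strengths:
        groups.setdefault(sample.matrix[idx[h]].tobytes(), []).append(h)
    strengths = dict(profile.strengths)
    for members in groups.values():
        mean = float(np.mean([profile.strengths[h] for h in members]))
        for h in members:
            strengths[h] = mean
    total = sum(strengths.values())
    probabilities = {h: v / total for h, v in strengths.items()}
    return RecombProfile(strengths, probabilities, profile.hotspot_id)


def sample_profile(sample: HaplotypeSample, hotspot_id: str | None = None) -> RecombProfile:
    """Walk a sample's true ARG and symmetrize the resulting profile."""
    hid = hotspot_id or (sample.scenario.tag or "hotspot")
    return symmetrize_profile(walk_profile(sample.true_arg, hid), sample)


def classify_hot_cold(profile: RecombProfile) -> tuple[dict[str, str], bool]:
    """Label each haplotype hot/cold by an exact 1-D 2-means split of V_p.

    The optimal split of the sorted values (minimum within-cluster sum of
    squares, exact scan over all split points) defines two clusters; the
    cluster with the larger mean is called "hot".  Returns the label map
    and a degeneracy flag: when all values are equal (no split exists) the
    labels are all "cold" and the flag is set.
    """
    ids = profile.haplotype_ids
    if len(ids) < 4:
        raise ValueError("classification needs at least 4 haplotypes")
    v = profile.values("probabilities")
    order = np.argsort(v, kind="stable")
    x = v[order]
    if x[0] == x[-1]:
        return {h: "cold" for h in ids}, True
    # prefix sums give the within-cluster SSE of every split in O(n)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    n = x.size
    best_k, best_cost = 1, np.inf
    for k in range(1, n):
        left = csq[k - 1] - csum[k - 1] ** 2 / k
        right = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        cost = left + right
        if cost < best_cost - 1e-15:
            best_cost, best_k = cost, k
    labels = {}
    for rank, i in enumerate(order):
        labels[ids[i]] = "cold" if rank < best_k else "hot"
    return labels, False


def confusion_metrics(
    pred: dict[str, str], truth: dict[str, str], tag: str = ""
) -> SampleMetrics:
    """Sensitivity/specificity/accuracy of hot/cold calls against truth.

    A rate whose denominator is empty (truth all one class) is reported as
    NaN, not 0.
    """
    if set(pred) != set(truth):
        raise ValueError("prediction and truth cover different haplotypes")
    tp = sum(1 for h in pred if pred[h] == "hot" and truth[h] == "hot")
    tn = sum(1 for h in pred if pred[h] == "cold" and truth[h] == "cold")
    fp = sum(1 for h in pred if pred[h] == "hot" and truth[h] == "cold")
    fn = sum(1 for h in pred if pred[h] == "cold" and truth[h] == "hot")
    n_hot, n_cold = tp + fn, tn + fp
    return SampleMetrics(
        tag=tag,
        sensitivity=tp / n_hot if n_hot else float("nan"),
        specificity=tn / n_cold if n_cold else float("nan"),
        accuracy=(tp + tn) / len(pred),
        n_hot=n_hot,
        n_cold=n_cold,
    )


def roc_auc(scores, labels) -> RocCurve:
    """ROC of scores against binary labels; AUC by the rank (Mann-Whitney) formula.

    Ties receive half-credit (midrank), so the AUC equals the normalized
    Mann-Whitney U statistic.  Raises if only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = pd.Series(s).rank(method="average").to_numpy()
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    tpr = np.asarray([(s[y] >= t).mean() for t in thresholds])
    fpr = np.asarray([(s[~y] >= t).mean() for t in thresholds])
    return RocCurve(thresholds, tpr, fpr, float(auc))


def _evaluate_one(scenario: Scenario) -> SampleMetrics:
    sample = simulate_sample(scenario)
    profile = sample_profile(sample)
    pred, _ = classify_hot_cold(profile)
    return confusion_metrics(pred, sample.truth, tag=scenario.tag)


def run_experiment(grid, seed: int = 0) -> pd.DataFrame:
    """Simulate → walk → classify → score every scenario of a grid.

    ``grid`` is a sequence of Scenarios (typically with replicate seeds
    already baked in, e.g. from ``make_scenario_grid``).  Per-replicate
    failures are logged and skipped, never aborting the sweep.  Returns a
    tidy DataFrame with one row per (scenario tag, replicate).
    """
    rows = []
    for i, sc in enumerate(grid):
        if sc.mode != "two-allele":
            continue  # hot/cold classification needs both classes
        try:
            m = _evaluate_one(sc)
        except Exception as exc:  # noqa: BLE001 - sweep must survive
            logger.warning("replicate %d (%s) failed: %s", i, sc.tag, exc)
            continue
        rows.append(
            {
                "scenario": sc.tag,
                "rep_seed": sc.seed,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "n_hot": m.n_hot,
                "n_cold": m.n_cold,
            }
        )
    return pd.DataFrame(rows)


def dip_experiment(
    n_two_allele: int = 50,
    n_no_variation: int = 50,
    *,
    base_seed: int = 77_000,
    n_null: int = 10_000,
    null_seed: int = 20150901,
    threshold: float = DIP_THRESHOLD,
    scenario_kwargs: dict | None = None,
) -> pd.DataFrame:
    """The unimodality-filter experiment behind the dip ROC.

    Simulates ``n_two_allele`` two-allele samples and ``n_no_variation``
    no-variation samples (alternating all-hot / all-cold), walks each true
    ARG, dip-tests each symmetrized strength profile against the uniform
    Monte-Carlo null, and returns one row per sample with its dip,
    -log10(p) score, variant/non-variant label and keep/drop decision at
    ``threshold``.
    """
    kw = scenario_kwargs or {}
    rows = []
    for i in range(n_two_allele + n_no_variation):
        if i < n_two_allele:
            mode, variant = "two-allele", True
        else:
            mode = "all-hot" if (i - n_two_allele) % 2 else "all-cold"
            variant = False
        sc = Scenario(seed=base_seed + i, mode=mode, tag=f"dip-{mode}-{i}", **kw)
        sample = simulate_sample(sc)
        profile = sample_profile(sample)
        vp = profile.values("probabilities")
        hot = np.asarray([sample.truth[h] == "hot" for h in profile.haplotype_ids])
        mean_hot = float(vp[hot].mean()) if hot.any() else float("nan")
        mean_cold = float(vp[~hot].mean()) if (~hot).any() else float("nan")
        try:
            d = dip_statistic(vp)
            res = dip_pvalue(d, vp.size, n_null=n_null, seed=null_seed)
            neg_log10_p = res.neg_log10_p
            dip = res.dip
        except ValueError:
            # a perfectly flat profile carries no evidence of variation
            dip, neg_log10_p = float("nan"), 0.0
        rows.append(
            {
                "sample": i,
                "mode": mode,
                "variant": variant,
                "dip": dip,
                "neg_log10_p": neg_log10_p,
                "kept": bool(neg_log10_p >= threshold),
                "mean_vp_hot": mean_hot,
                "mean_vp_cold": mean_cold,
            }
        )
    return pd.DataFrame(rows)
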