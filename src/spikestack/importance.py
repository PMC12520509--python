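"""Grouped permutation feature importance and region decomposition.

The contribution of a feature group (all features of one temporal
resolution, one neuron, or one anatomical region) is measured as the
increase in out-of-fold cross-entropy when that group's features are
permuted jointly across the held-out trials of each outer fold and the
predictions are re-propagated through the fitted fold models. Because
the feature map is linear per neuron, permuting a neuron's rows of the
spike pattern and re-extracting features is identical to permuting
that neuron's feature block, which is what is done here.

Region analysis decomposes the two regions' contributions by
inclusion-exclusion (commonality analysis on the loss scale). A
region's total contribution is the cross-entropy reduction achieved by
having that region's features intact, relative to inputs with *all*
neurons permuted; in terms of the measured permutation damages D_X
(loss increase when group X is permuted),

    C_CA3   = D_both - D_CA1      (only CA3 intact)
    C_CA1   = D_both - D_CA3      (only CA1 intact)
    C_both  = D_both              (everything intact vs nothing)

    redundancy  = C_CA3 + C_CA1 - C_both
    unique_CA3  = C_CA3 - redundancy
    unique_CA1  = C_CA1 - redundancy

so unique_CA3 + unique_CA1 + redundancy == C_both exactly (algebraic
identity, not an estimate), and two regions that duplicate each
other's information — either of which alone supports decoding — show
large redundancy and small unique terms. Per-neuron averages divide
each region's total contribution by its neuron count to balance
unequal region sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import log_loss

__all__ = [
    "FeatureGroup",
    "ContributionDecomposition",
    "permutation_importance",
    "resolution_profile",
    "region_decomposition",
    "compare_region_means",
]


@dataclass(frozen=True)
class FeatureGroup:
    """A named group of model inputs permuted jointly.

    ``kind='resolution'`` groups every feature of the listed resolutions
    (``members`` are segment counts m+1); ``kind`` 'neuron' or 'region'
    groups every feature of the listed neuron indices, across all
    resolutions.
    """

    name: str
    kind: str  # 'resolution' | 'neuron' | 'region'
    members: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("resolution", "neuron", "region"):
            raise ValueError(f"unknown grouping kind {self.kind!r}")


def _permuted_category_loss(
    cat_result, features: dict, group: FeatureGroup, perm_rngs, segments, n_neurons
) -> float:
    """Out-of-fold cross-entropy with the group permuted within each fold's
    held-out trials."""
    oof = np.empty(len(cat_result.y_true))
    for fold, rng in zip(cat_result.folds, perm_rngs):
        te = fold.test_idx
        pi = rng.permutation(len(te))
        model = fold.model
        if group.kind == "resolution":
            Z = model.base_probabilities({m: features[m][te] for m in segments})
            for mi, m in enumerate(segments):
                if m in group.members:
                    Z[:, mi] = Z[pi, mi]
            oof[te] = (
                model.meta.predict_proba(Z) if model.meta is not None else Z[:, 0]
            )
        else:
            X_by_m = {}
            for m in segments:
                X = features[m][te].copy()
                J = X.shape[1] // n_neurons
                for n in group.members:
                    block = slice(n * J, (n + 1) * J)
                    X[:, block] = X[pi, block]
                X_by_m[m] = X
            oof[te] = model.predict_proba(X_by_m)
    return log_loss(cat_result.y_true, oof, labels=[0, 1])


def permutation_importance(
    result,
    groups: list,
    n_permutations: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean cross-entropy increase per (category, group).

    For each permutation draw, each group's features are permuted
    jointly across the held-out trials of every outer fold; the delta is
    the permuted out-of-fold cross-entropy minus the intact one,
    averaged over ``n_permutations``. Reproducible from ``seed``.

    Returns a tidy frame with columns category, group, kind, raw_delta,
    normalized_share (negative deltas floored at 0 before normalizing
    within each (category, kind)), and n_permutations.
    """
    n_neurons = result.categories[0].folds[0].model.n_neurons
    segments = tuple(result.config.segments)
    for g in groups:
        if g.kind == "resolution":
            unknown = set(g.members) - set(segments)
        else:
            unknown = {n for n in g.members if not 0 <= n < n_neurons}
        if unknown:
            raise ValueError(f"group {g.name!r} references unknown members {unknown}")
    master = np.random.default_rng(seed)
    rows = []
    for cat in result.categories:
        base_loss = log_loss(cat.y_true, cat.oof_prob, labels=[0, 1])
        for g in groups:
            deltas = np.empty(n_permutations)
            for i in range(n_permutations):
                perm_rngs = [
                    np.random.default_rng(int(master.integers(2**31 - 1)))
                    for _ in cat.folds
                ]
                loss = _permuted_category_loss(
                    cat, result.features, g, perm_rngs, segments, n_neurons
                )
                deltas[i] = loss - base_loss
            rows.append(
                {
                    "category": cat.category,
                    "group": g.name,
                    "kind": g.kind,
                    "raw_delta": float(deltas.mean()),
                    "n_permutations": n_permutations,
                }
            )
    df = pd.DataFrame(rows)
    df["floored"] = df["raw_delta"].clip(lower=0.0)
    totals = df.groupby(["category", "kind"])["floored"].transform("sum")
    df["normalized_share"] = np.where(totals > 0, df["floored"] / totals, 0.0)
    return df.drop(columns="floored")


def resolution_profile(
    result, n_permutations: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Normalized contribution of each temporal resolution.

    One group per resolution; shares are normalized to sum to 1 within
    each category and additionally averaged across categories
    (column ``mean_share`` of the returned per-resolution frame).
    """
    groups = [
        FeatureGroup(name=f"res_{m}", kind="resolution", members=(m,))
        for m in result.config.segments
    ]
    df = permutation_importance(result, groups, n_permutations, seed)
    order = {f"res_{m}": i for i, m in enumerate(result.config.segments)}
    prof = (
        df.groupby("group", sort=False)
        .agg(mean_share=("normalized_share", "mean"), mean_delta=("raw_delta", "mean"))
        .reset_index()
    )
    prof["segments"] = prof["group"].str.removeprefix("res_").astype(int)
    window = result.bases[result.config.segments[0]].window_ms
    prof["resolution_ms"] = window / prof["segments"]
    return prof.sort_values("group", key=lambda s: s.map(order)).reset_index(drop=True)


@dataclass(frozen=True)
class ContributionDecomposition:
    """Unique/redundant split of two regions' loss-based contributions.

    ``c_ca3``/``c_ca1`` are sole-region contributions (loss reduction of
    that region's intact features relative to fully permuted inputs);
    ``c_both`` is the combined contribution.
    """

    c_ca3: float
    c_ca1: float
    c_both: float

    @property
    def redundancy(self) -> float:
        return self.c_ca3 + self.c_ca1 - self.c_both

    @property
    def unique_ca3(self) -> float:
        return self.c_ca3 - self.redundancy

    @property
    def unique_ca1(self) -> float:
        return self.c_ca1 - self.redundancy

    def shares(self) -> dict:
        """Percentage split of the combined contribution (floored at 0)."""
        parts = {
            "unique_ca3": max(self.unique_ca3, 0.0),
            "redundancy": max(self.redundancy, 0.0),
            "unique_ca1": max(self.unique_ca1, 0.0),
        }
        total = sum(parts.values())
        if total == 0:
            return {k: 0.0 for k in parts}
        return {k: 100.0 * v / total for k, v in parts.items()}


def region_decomposition(
    result,
    regions=None,
    n_permutations: int = 50,
    seed: int = 0,
) -> dict:
    """CA3/CA1 unique and redundant contributions.

    Measures the permutation damage of (i) all CA3 neurons' features,
    (ii) all CA1 neurons', and (iii) both together, converts the
    damages into sole-region contributions by inclusion-exclusion, and
    applies the redundancy algebra per category. Returns per-category
    decompositions, category-averaged percentage shares, and
    per-neuron normalized region contributions.
    """
    regions = tuple(regions) if regions is not None else tuple(result.regions)
    ca3 = tuple(i for i, r in enumerate(regions) if r == "CA3")
    ca1 = tuple(i for i, r in enumerate(regions) if r == "CA1")
    if not ca3 or not ca1:
        raise ValueError("both regions must contain at least one neuron")
    groups = [
        FeatureGroup("CA3", "region", ca3),
        FeatureGroup("CA1", "region", ca1),
        FeatureGroup("both", "region", ca3 + ca1),
    ]
    df = permutation_importance(result, groups, n_permutations, seed)
    per_category = {}
    share_rows, per_neuron_rows = [], []
    for cat, sub in df.groupby("category", sort=False):
        d = dict(zip(sub["group"], sub["raw_delta"]))
        dec = ContributionDecomposition(
            c_ca3=d["both"] - d["CA1"],
            c_ca1=d["both"] - d["CA3"],
            c_both=d["both"],
        )
        per_category[cat] = dec
        share_rows.append(dec.shares())
        per_neuron_rows.append(
            {"CA3": dec.c_ca3 / len(ca3), "CA1": dec.c_ca1 / len(ca1)}
        )
    mean_shares = {
        k: float(np.mean([r[k] for r in share_rows])) for k in share_rows[0]
    }
    per_neuron = pd.DataFrame(per_neuron_rows, index=list(per_category))
    return {
        "per_category": per_category,
        "mean_shares_pct": mean_shares,
        "per_neuron": per_neuron,
        "raw": df,
    }


def compare_region_means(per_neuron_a: np.ndarray, per_neuron_b: np.ndarray):
    """Paired two-sided t-test between matched per-neuron contributions
    (e.g., CA3 vs CA1 across datasets/categories). Reported, not gating."""
    t, p = stats.ttest_rel(per_neuron_a, per_neuron_b)
    return {"t": float(t), "p": float(p), "n": len(per_neuron_a)}
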