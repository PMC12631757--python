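"""Model-agnostic Shapley attribution over feature groups and the
HHT-vs-raw importance ratio R.

The estimator is KernelSHAP: for a target sample x and a single background
sample b, coalitions z in {0,1}^M select which feature groups keep their
target values (masked groups are replaced by the background's values). The
group attributions phi solve the weighted least-squares problem

    min sum_z w(z) (phi0 + z . phi - f(masked(z)))^2,
    s.t. sum_g phi_g = f(x) - f(b),   phi0 = f(b),

with the Shapley kernel w(z) = (M-1) / (C(M,|z|) |z| (M-|z|)). With every
proper non-empty coalition enumerated (done whenever the budget covers all
2^M - 2 of them, and always for M <= 12) this reproduces exact Shapley
values; otherwise complete coalition-size classes are enumerated from the
extremes inward (where the kernel puts most mass) and the remaining budget is
sampled. Local accuracy (the constraint above) holds on every run by
construction.

The importance ratio compares mean |SHAP| over HHT-derived feature groups
against raw-signal groups:  R = mean_hht / mean_raw. R > 1 means HHT features
dominate the model's decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .exceptions import (
    ConditioningError,
    PartitionError,
    ProtocolError,
    UndefinedRatioError,
)
from .network import HhtSannClassifier, features_for_epochset
from .signal_io import EpochSet

EXHAUSTIVE_MAX_GROUPS = 12


@dataclass
class ImportanceReport:
    """Per-group mean |SHAP| with the HHT-vs-original ratio R."""

    per_group_importance: dict[str, float]
    group_partition: dict[str, str]  # group id -> "hht" | "original"
    mean_hht: float
    mean_original: float
    ratio_R: float
    n_targets: int
    dominant: bool  # original importance at solver-noise scale; R unreliable

    def as_dict(self) -> dict:
        return {
            "per_group_importance": self.per_group_importance,
            "group_partition": self.group_partition,
            "mean_hht": self.mean_hht,
            "mean_original": self.mean_original,
            "ratio_R": self.ratio_R,
            "n_targets": self.n_targets,
            "dominant": self.dominant,
        }


def _kernel_weight(M: int, k: int) -> float:
    return (M - 1) / (comb(M, k) * k * (M - k))


def _coalition_rows(M: int, n_coalitions: int, rng: np.random.Generator):
    """Binary coalition matrix Z and regression weights.

    Enumerates complete size classes from the extremes inward while the
    budget allows (size classes 1 and M-1 carry the largest kernel mass),
    then samples the rest in proportion to the remaining mass.
    """
    full = 2 ** M - 2
    if full <= n_coalitions:
        Z = np.zeros((full, M))
        w = np.empty(full)
        row = 0
        for k in range(1, M):
            wk = _kernel_weight(M, k)
            for subset in combinations(range(M), k):
                Z[row, list(subset)] = 1.0
                w[row] = wk
                row += 1
        return Z, w

    sizes = list(range(1, M))
    order = sorted(sizes, key=lambda k: min(k, M - k))
    class_mass = {k: _kernel_weight(M, k) * comb(M, k) for k in sizes}
    rows: list[np.ndarray] = []
    weights: list[float] = []
    budget = n_coalitions
    remaining: list[int] = []
    for k in order:
        if comb(M, k) <= budget - len(remaining):
            for subset in combinations(range(M), k):
                z = np.zeros(M)
                z[list(subset)] = 1.0
                rows.append(z)
                weights.append(_kernel_weight(M, k))
            budget -= comb(M, k)
        else:
            remaining.append(k)
    if remaining and budget > 0:
        mass = np.array([class_mass[k] for k in remaining])
        mass /= mass.sum()
        counts = rng.multinomial(budget, mass)
        for k, n_k in zip(remaining, counts):
            if n_k == 0:
                continue
            # uniform subsets within the class; weight = class mass / draws
            per_row_w = class_mass[k] / n_k
            for _ in range(n_k):
                z = np.zeros(M)
                z[rng.choice(M, size=k, replace=False)] = 1.0
                rows.append(z)
                weights.append(per_row_w)
    return np.array(rows), np.array(weights)


def _solve_constrained_wls(Z, w, y, total):
    """Solve the kernel regression with the efficiency constraint."""
    M = Z.shape[1]
    Zr = Z[:, :-1] - Z[:, -1:]
    yr = y - Z[:, -1] * total
    sw = np.sqrt(w)[:, None]
    sol, _, rank, _ = np.linalg.lstsq(sw * Zr, (sw[:, 0]) * yr, rcond=None)
    if rank < M - 1:
        raise ConditioningError(
            f"coalition design rank {rank} < {M - 1}; add coalitions"
        )
    phi = np.empty(M)
    phi[:-1] = sol
    phi[-1] = total - sol.sum()
    return phi


def kernel_shap(
    predict_fn,
    background: np.ndarray,
    targets,
    groups: list[np.ndarray],
    n_coalitions: int = 2048,
    seed: int = 0,
) -> np.ndarray:
    """Grouped Shapley values for each target against one background sample.

    Parameters
    ----------
    predict_fn : callable
        Maps an (n, n_features) array to n scalar model outputs.
    background : 1-D array
        The single background sample; masked groups take its values.
    targets : sequence of 1-D arrays
        Samples to explain.
    groups : list of index arrays
        A partition of ``range(n_features)``; one attribution per group.
    n_coalitions : int
        Evaluation budget per target (all coalitions are enumerated whenever
        ``2^M - 2`` fits inside it, and always when ``M <= 12``).
    seed : int
        Coalition-sampling seed.

    Returns
    -------
    ndarray, shape (n_targets, n_groups)
    """
    background = np.asarray(background, dtype=np.float64).ravel()
    targets = [np.asarray(t, dtype=np.float64).ravel() for t in targets]
    M = len(groups)
    if M < 1:
        raise PartitionError("need at least one feature group")
    covered = np.concatenate([np.asarray(g) for g in groups])
    if len(np.unique(covered)) != covered.size or covered.size != background.size:
        raise PartitionError("groups must partition the feature set exactly")
    if n_coalitions < M + 2:
        raise ProtocolError(f"n_coalitions must be >= n_groups + 2 = {M + 2}")
    rng = np.random.default_rng(seed)
    budget = max(n_coalitions, 2 ** M - 2) if M <= EXHAUSTIVE_MAX_GROUPS else n_coalitions
    Z, w = _coalition_rows(M, budget, rng)

    f_bg = float(np.asarray(predict_fn(background[None, :])).ravel()[0])

    def solve_target(x, Z, w):
        masked = np.tile(background, (Z.shape[0], 1))
        for g, idx in enumerate(groups):
            sel = Z[:, g] == 1.0
            masked[np.ix_(sel, np.asarray(idx))] = x[np.asarray(idx)]
        f_x = float(np.asarray(predict_fn(x[None, :])).ravel()[0])
        y = np.asarray(predict_fn(masked), dtype=np.float64).ravel() - f_bg
        return _solve_constrained_wls(Z, w, y, f_x - f_bg)

    out = np.empty((len(targets), M))
    for ti, x in enumerate(targets):
        try:
            out[ti] = solve_target(x, Z, w)
        except ConditioningError:
            if M <= EXHAUSTIVE_MAX_GROUPS and Z.shape[0] < 2 ** M - 2:
                # degenerate sampled design: fall back to full enumeration
                Z, w = _coalition_rows(M, 2 ** M - 2, rng)
                out[ti] = solve_target(x, Z, w)
            else:
                raise
    return out


def importance_ratio(
    shap_values: np.ndarray,
    group_ids: list[str],
    partition: dict[str, str],
    dominance_tol: float = 1e-6,
) -> ImportanceReport:
    """Aggregate |SHAP| per group and form R = mean(hht) / mean(original).

    ``partition`` maps each group id to ``"hht"`` or ``"original"``; both
    sides must be non-empty. A zero original-side mean raises
    :class:`UndefinedRatioError`; an original-side mean at solver-noise scale
    relative to the HHT side sets the ``dominant`` flag.
    """
    shap_values = np.atleast_2d(np.asarray(shap_values, dtype=np.float64))
    if shap_values.shape[1] != len(group_ids):
        raise PartitionError("one column per group required")
    per_group = {
        gid: float(np.mean(np.abs(shap_values[:, i])))
        for i, gid in enumerate(group_ids)
    }
    hht = [v for gid, v in per_group.items() if partition.get(gid) == "hht"]
    orig = [v for gid, v in per_group.items() if partition.get(gid) == "original"]
    if not hht or not orig:
        raise PartitionError("both the hht and original partitions must be non-empty")
    mean_hht = float(np.mean(hht))
    mean_orig = float(np.mean(orig))
    if mean_orig == 0.0:
        raise UndefinedRatioError("original-feature importance is exactly zero")
    return ImportanceReport(
        per_group_importance=per_group,
        group_partition={gid: partition[gid] for gid in group_ids},
        mean_hht=mean_hht,
        mean_original=mean_orig,
        ratio_R=mean_hht / mean_orig,
        n_targets=shap_values.shape[0],
        dominant=mean_orig <= dominance_tol * max(mean_hht, 1e-300),
    )


def feature_groups_from_index(channel_index) -> tuple[list[str], dict]:
    """Group flattened feature columns by plane.

    Each plane (raw channel, or one IMF's amplitude/frequency plane of one
    electrode) is a single column of the feature matrix; its group collects
    the column's entries across all pooled time steps. Raw planes go to the
    ``original`` partition, the rest to ``hht``.
    """
    ids: list[str] = []
    partition: dict[str, str] = {}
    for key in channel_index:
        if key.kind == "raw":
            gid = f"{key.electrode}:raw"
            partition[gid] = "original"
        else:
            gid = f"{key.electrode}:imf{key.imf_index + 1}:{key.kind}"
            partition[gid] = "hht"
        ids.append(gid)
    return ids, partition


def explain_model(
    model: HhtSannClassifier,
    es: EpochSet,
    n_targets: int = 10,
    seed: int = 0,
    n_coalitions: int = 2048,
    features: np.ndarray | None = None,
    channel_index=None,
) -> ImportanceReport:
    """Attribute a trained model's MDD probability to raw vs HHT planes.

    One randomly chosen epoch serves as the background; ``n_targets`` other
    epochs are explained; attributions are aggregated to mean |SHAP| per
    plane and the importance ratio R.
    """
    if features is None:
        features, channel_index = features_for_epochset(es, model.cfg)
    if channel_index is None:
        channel_index = model.channel_index
    if es.n_epochs < n_targets + 1:
        raise ProtocolError(
            f"need at least {n_targets + 1} epochs, got {es.n_epochs}"
        )
    Tp, C = features.shape[1], features.shape[2]
    ids, partition = feature_groups_from_index(channel_index)
    # column c of the (T' x C) matrix occupies flat indices c, C+c, 2C+c, ...
    groups = [np.arange(Tp) * C + c for c in range(C)]

    def predict_fn(flat: np.ndarray) -> np.ndarray:
        X = flat.reshape(-1, Tp, C)
        return model.predict_proba(X)[:, 1]

    rng = np.random.default_rng(seed)
    chosen = rng.choice(es.n_epochs, size=n_targets + 1, replace=False)
    bg, targets = chosen[0], chosen[1:]
    flat = features.reshape(es.n_epochs, -1)
    shap_values = kernel_shap(
        predict_fn,
        flat[bg],
        [flat[t] for t in targets],
        groups,
        n_coalitions=n_coalitions,
        seed=seed,
    )
    return importance_ratio(shap_values, ids, partition)
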