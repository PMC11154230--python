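"""Downstream analyses on execution modes.

Time of death (ToD) is the midpoint of the times at which the apoptosis
completion marker (cleaved PARP) first reaches 10% and 90% of its maximum,
ToD = (T10 + T90) / 2.  Knockdown experiments rerun the ensemble with a
species' initial abundance reduced and compare per-mode ToD and reaction-rate
peak statistics.  A measured rate constant updates mode probabilities through
Bayes' rule over per-mode kernel density estimates, and a gradient-boosted
tree classifier quantifies how well log10 parameter values alone predict mode
membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .network import (ParameterEnsemble, ReactionNetwork, Trajectory,
                      apply_knockdown, simulate)

__all__ = [
    "ToDResult",
    "PeakStats",
    "ModeDensityModel",
    "time_of_death",
    "knockdown_experiment",
    "peak_stats",
    "ensemble_peak_stats",
    "update_mode_probabilities",
    "classify_modes",
    "ClassifierReport",
]


@dataclass(frozen=True)
class ToDResult:
    """First-crossing times of 10% / 90% of the trajectory maximum."""

    t10: float
    t90: float

    @property
    def tod(self) -> float:
        return 0.5 * (self.t10 + self.t90)


def _first_crossing(t: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """First upward crossing of threshold, linearly interpolated."""
    above = y >= threshold
    if above[0]:
        return float(t[0])
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        raise ValueError("trajectory never reaches threshold")
    i = idx[0]
    frac = (threshold - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def time_of_death(traj: Trajectory, species: str = "cPARP") -> ToDResult | None:
    """ToD of a completion-marker trajectory; None if the signal never rises.

    Invariant to positive rescaling of the trajectory: only the fractional
    10% / 90% thresholds of the maximum matter.
    """
    y = traj.species(species)
    ymax = y.max()
    if not ymax > 0:
        return None
    t = traj.time_grid
    t10 = _first_crossing(t, y, 0.10 * ymax)
    t90 = _first_crossing(t, y, 0.90 * ymax)
    return ToDResult(t10=t10, t90=t90)


def knockdown_experiment(net: ReactionNetwork, ensemble: ParameterEnsemble,
                         assignments: np.ndarray, species: str, fraction: float,
                         target: str, time_grid: np.ndarray,
                         rtol: float = 1e-6, atol: float = 1e-6,
                         ) -> dict[int, dict[str, float]]:
    """Per-mode ToD comparison between wild type and a knockdown condition.

    Simulates every ensemble member under both conditions and reports, per
    mode: mean and sd of wild-type and knockdown ToD, and
    delta_tod = mean(KD) - mean(WT).  Members whose ToD is undefined (flat
    marker trajectory) are dropped from that mode's statistics.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(ensemble):
        raise ValueError("assignments must match ensemble size")
    kd_net = apply_knockdown(net, species, fraction)
    tod_wt = np.full(len(ensemble), np.nan)
    tod_kd = np.full(len(ensemble), np.nan)
    for i, pv in enumerate(ensemble):
        for which, network, store in (("WT", net, tod_wt), ("KD", kd_net, tod_kd)):
            traj = simulate(network, pv, time_grid, rtol=rtol, atol=atol)
            res = time_of_death(traj, target)
            if res is None:
                warnings.warn(f"member {i} ({which}): ToD undefined")
            else:
                store[i] = res.tod
    out: dict[int, dict[str, float]] = {}
    for mode in np.unique(assignments):
        sel = assignments == mode
        wt = tod_wt[sel]
        kd = tod_kd[sel]
        ok = np.isfinite(wt) & np.isfinite(kd)
        out[int(mode)] = {
            "n": int(sel.sum()),
            "tod_wt_mean": float(np.mean(wt[ok])) if ok.any() else float("nan"),
            "tod_wt_sd": float(np.std(wt[ok], ddof=0)) if ok.any() else float("nan"),
            "tod_kd_mean": float(np.mean(kd[ok])) if ok.any() else float("nan"),
            "tod_kd_sd": float(np.std(kd[ok], ddof=0)) if ok.any() else float("nan"),
            "delta_tod": float(np.mean(kd[ok]) - np.mean(wt[ok]))
            if ok.any() else float("nan"),
        }
    return out


@dataclass(frozen=True)
class PeakStats:
    """Peak height/time of a perturbed rate trajectory vs. a reference.

    Percent changes are signed: 100 * (perturbed - reference) / reference.
    """

    peak_reference: float
    peak_perturbed: float
    time_to_peak_reference: float
    time_to_peak_perturbed: float

    @property
    def pct_change_peak(self) -> float:
        return 100.0 * (self.peak_perturbed - self.peak_reference) \
            / self.peak_reference

    @property
    def pct_change_time(self) -> float:
        return 100.0 * (self.time_to_peak_perturbed - self.time_to_peak_reference) \
            / self.time_to_peak_reference


def peak_stats(rate_reference: np.ndarray, rate_perturbed: np.ndarray,
               time_grid: np.ndarray) -> PeakStats:
    """Compare peak value and first-occurrence peak time of two rate curves."""
    ref = np.asarray(rate_reference, dtype=float)
    pert = np.asarray(rate_perturbed, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    if not (len(ref) == len(pert) == len(t)):
        raise ValueError("trajectories and time grid must share a length")
    if not ref.max() > 0:
        raise ValueError("reference peak must be positive")
    i_ref = int(np.argmax(ref))
    i_pert = int(np.argmax(pert))
    return PeakStats(
        peak_reference=float(ref[i_ref]),
        peak_perturbed=float(pert[i_pert]),
        time_to_peak_reference=float(t[i_ref]),
        time_to_peak_perturbed=float(t[i_pert]),
    )


def ensemble_peak_stats(pairs: Sequence[PeakStats]) -> dict[str, float]:
    """Median and interquartile range of per-member percent changes."""
    df = np.array([p.pct_change_peak for p in pairs])
    dt = np.array([p.pct_change_time for p in pairs])
    q = lambda a, p: float(np.percentile(a, p))  # noqa: E731
    return {
        "median_pct_change_peak": float(np.median(df)),
        "iqr_pct_change_peak": (q(df, 25), q(df, 75)),
        "median_pct_change_time": float(np.median(dt)),
        "iqr_pct_change_time": (q(dt, 25), q(dt, 75)),
    }


class ModeDensityModel:
    """Per-mode prior + 1-D density of a single rate constant (log10 scale).

    After measuring a parameter value s, the posterior over modes is
    P(mode_i | s) = p_i X_i(s) / sum_j p_j X_j(s), with X_i a Gaussian kernel
    density over the mode members' log10 parameter values (bandwidth by
    Scott's rule).
    """

    def __init__(self, priors: Mapping[int, float],
                 densities: Mapping[int, gaussian_kde],
                 param_name: str) -> None:
        total = sum(priors.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"mode priors must sum to 1, got {total}")
        if set(priors) != set(densities):
            raise ValueError("priors and densities must cover the same modes")
        self.priors = dict(priors)
        self.densities = dict(densities)
        self.param_name = param_name

    @classmethod
    def from_modes(cls, ensemble: ParameterEnsemble, assignments: np.ndarray,
                   param_name: str) -> "ModeDensityModel":
        from .modes import mode_probabilities

        assignments = np.asarray(assignments)
        values = np.log10([pv.values[param_name] for pv in ensemble])
        priors = mode_probabilities(assignments, ensemble)
        densities = {
            mode: gaussian_kde(values[assignments == mode])
            for mode in priors
        }
        return cls(priors, densities, param_name)

    def density_at(self, s: float) -> dict[int, float]:
        ls = np.log10(s)
        return {m: float(kde(ls)[0]) for m, kde in self.densities.items()}


def update_mode_probabilities(model: ModeDensityModel,
                              s: float) -> dict[int, float]:
    """Bayes update of mode probabilities given a measured parameter value.

    Invariant to a common positive rescaling of the densities; errors if the
    measurement is incompatible with every mode (all densities zero).
    """
    dens = model.density_at(s)
    numer = {m: model.priors[m] * dens[m] for m in dens}
    z = sum(numer.values())
    if z <= 0:
        raise ValueError(
            f"measured value {s} has zero density under every mode")
    return {m: v / z for m, v in numer.items()}


@dataclass
class ClassifierReport:
    accuracy: float
    importance: dict[str, float]       # total-gain, descending
    n_train: int
    n_test: int

    def top_parameter(self) -> str:
        return next(iter(self.importance))


def classify_modes(ensemble: ParameterEnsemble, assignments: np.ndarray,
                   split_fraction: float = 0.75, seed: int = 0,
                   learning_rate: float = 0.1, n_estimators: int = 100,
                   ) -> ClassifierReport:
    """Gradient-boosted trees predicting mode membership from log10 rates.

    Reports held-out accuracy and per-parameter total-gain importance.
    The defaults (0.75 train split, learning rate 0.1, 100 estimators,
    softmax multiclass objective, L1/L2 regularization 1, 16 histogram bins)
    are exposed for tuning.
    """
    from sklearn.model_selection import train_test_split
    from xgboost import XGBClassifier

    assignments = np.asarray(assignments)
    uniq = np.unique(assignments)
    if len(uniq) < 2:
        raise ValueError("need at least 2 modes to classify")
    if len(ensemble) < 20:
        raise ValueError("need at least 20 parameter vectors")
    names = ensemble.parameter_names()
    X = np.log10(ensemble.to_array(names))
    y = np.searchsorted(uniq, assignments)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split_fraction, random_state=seed, stratify=y)
    clf = XGBClassifier(
        booster="gbtree",
        objective="multi:softmax",
        num_class=len(uniq),
        eval_metric="merror",
        learning_rate=learning_rate,
        n_estimators=n_estimators,
        reg_alpha=1,
        reg_lambda=1,
        tree_method="hist",
        max_bin=16,
        random_state=seed,
    )
    clf.fit(X_tr, y_tr)
    accuracy = float((clf.predict(X_te) == y_te).mean())
    booster = clf.get_booster()
    booster.feature_names = list(names)
    gains = booster.get_score(importance_type="total_gain")
    importance = {p: float(gains.get(p, 0.0)) for p in names}
    importance = dict(sorted(importance.items(), key=lambda kv: -kv[1]))
    return ClassifierReport(
        accuracy=accuracy,
        importance=importance,
        n_train=len(y_tr),
        n_test=len(y_te),
    )
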