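"""Synthetic multi-condition genotype/expression data generator.

Generates genotype-like predictors (binomial dosages at allele frequencies
drawn uniformly from a minor-allele-frequency range) and multi-condition
outcomes under five effect-sharing scenarios:

* A "equal_effects"       — each causal variant has the same effect in every
                            condition;
* B "independent_effects" — causal effects drawn independently per condition;
* C "mostly_null"         — causal effects in condition 1 only;
* D "equal_effects_null"  — equal effects within a leading subgroup of
                            conditions, none elsewhere;
* E "shared_subgroups"    — per causal variant a fair coin picks one of two
                            condition subgroups; effects are shared within
                            the chosen subgroup with constant correlation 0.8
                            and are zero outside it. The leading subgroup
                            carries the high signal, the complement the low
                            signal.

Effect columns are rescaled on the realised training genotypes so the causal
variants explain exactly the target proportion of variance (PVE) in each
condition, and residual variances are set so every condition has total
variance 1 — standardized prediction RMSEs are then directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mrmash.datasets import RegressionDataset

SCENARIOS = {
    "A": "equal_effects",
    "B": "independent_effects",
    "C": "mostly_null",
    "D": "equal_effects_null",
    "E": "shared_subgroups",
}
_SUBGROUP_CORR = 0.8  # within-subgroup effect correlation in scenario E


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulated dataset.

    ``n`` is the total number of samples; a fraction ``test_fraction`` is
    held out as a fully observed test split. ``pve_high`` is the per-condition
    proportion of variance explained by the causal variants in high-signal
    conditions (all conditions in scenarios A and B); ``pve_low`` applies to
    the second subgroup in scenario E. ``subgroup1`` lists 1-based condition
    indices of the leading subgroup (scenarios D and E). ``missing_rate``
    masks training outcome entries independently at random.
    """

    scenario: str = "A"
    n: int = 600
    p: int = 200
    r: int = 10
    n_causal: int = 5
    pve_high: float = 0.20
    pve_low: float = 0.05
    subgroup1: tuple[int, ...] = (1, 2, 3)
    missing_rate: float = 0.0
    test_fraction: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)
    resid_corr: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        scen = self.scenario.upper()
        if scen not in SCENARIOS:
            long_to_short = {v: k for k, v in SCENARIOS.items()}
            scen = long_to_short.get(self.scenario.lower(), None)
            if scen is None:
                raise ValueError(f"unknown scenario {self.scenario!r}")
        object.__setattr__(self, "scenario", scen)
        if self.n_causal > self.p:
            raise ValueError("n_causal must not exceed p")
        if not (0 <= self.pve_high < 1 and 0 <= self.pve_low < 1):
            raise ValueError("PVE targets must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.test_fraction < 1:
            raise ValueError("test_fraction must lie in [0, 1)")
        sub = tuple(int(s) for s in self.subgroup1)
        if scen in ("D", "E") and any(s < 1 or s > self.r for s in sub):
            raise ValueError("subgroup1 must be a subset of 1..r")
        object.__setattr__(self, "subgroup1", sub)

    @property
    def n_train(self) -> int:
        return self.n - round(self.n * self.test_fraction)

    def pve_targets(self) -> np.ndarray:
        """Per-condition PVE target implied by the scenario."""
        targets = np.zeros(self.r)
        sub1 = np.asarray(self.subgroup1) - 1
        if self.scenario in ("A", "B"):
            targets[:] = self.pve_high
        elif self.scenario == "C":
            targets[0] = self.pve_high
        elif self.scenario == "D":
            targets[sub1] = self.pve_high
        else:  # E
            targets[:] = self.pve_low
            targets[sub1] = self.pve_high
        return targets


@dataclass
class SimulatedDataset:
    """A simulated train/test pair together with its generating truth."""

    train: RegressionDataset
    test: RegressionDataset
    B_true: np.ndarray
    V_true: np.ndarray
    causal_indices: np.ndarray
    pve_realized: np.ndarray
    mafs: np.ndarray
    spec: ScenarioSpec
    causal_subgroup: np.ndarray | None = None  # scenario E: 1 or 2 per causal variant


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(n: int, p: int, maf_range=(0.05, 0.5), seed=0):
    """Binomial(2, MAF) dosage matrix with per-column MAF ~ Uniform(maf_range).

    Columns that come out constant (possible at extreme MAF and small n) are
    redrawn so downstream regressions are always defined. Returns the dosage
    matrix and the vector of sampled MAFs.
    """
    rng = _rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=p)
    X = rng.binomial(2, mafs[None, :], size=(n, p)).astype(float)
    if n > 1:
        for _ in range(100):
            const = np.ptp(X, axis=0) == 0
            if not const.any():
                break
            X[:, const] = rng.binomial(
                2, mafs[None, const], size=(n, int(const.sum()))
            )
    return X, mafs


def simulate_effects(spec: ScenarioSpec, causal_indices, rng=None):
    """Raw (pre-scaling) effect matrix for the causal variants.

    Returns ``(B_raw, causal_subgroup)``; the subgroup assignment is only
    populated for scenario E.
    """
    rng = _rng(spec.seed if rng is None else rng)
    causal = np.asarray(causal_indices, dtype=int)
    p, r = spec.p, spec.r
    B = np.zeros((p, r))
    sub1 = np.asarray(spec.subgroup1, dtype=int) - 1
    sub2 = np.setdiff1d(np.arange(r), sub1)
    subgroup = None
    scen = spec.scenario
    if scen == "A":
        B[causal, :] = rng.standard_normal(len(causal))[:, None]
    elif scen == "B":
        B[causal, :] = rng.standard_normal((len(causal), r))
    elif scen == "C":
        B[causal, 0] = rng.standard_normal(len(causal))
    elif scen == "D":
        if len(sub1) == 0:
            raise ValueError("scenario D requires a non-empty subgroup1")
        B[np.ix_(causal, sub1)] = rng.standard_normal(len(causal))[:, None]
    elif scen == "E":
        if len(sub1) == 0 or len(sub2) == 0:
            raise ValueError(
                "scenario E requires both subgroup1 and its complement to be non-empty"
            )
        chol = {
            1: np.linalg.cholesky(
                (1 - _SUBGROUP_CORR) * np.eye(len(sub1))
                + _SUBGROUP_CORR * np.ones((len(sub1), len(sub1)))
            ),
            2: np.linalg.cholesky(
                (1 - _SUBGROUP_CORR) * np.eye(len(sub2))
                + _SUBGROUP_CORR * np.ones((len(sub2), len(sub2)))
            ),
        }
        cols = {1: sub1, 2: sub2}
        subgroup = np.where(rng.random(len(causal)) < 0.5, 1, 2)
        # both subgroups must be represented or their PVE targets are unattainable
        while len(causal) >= 2 and len(set(subgroup)) < 2:
            subgroup = np.where(rng.random(len(causal)) < 0.5, 1, 2)
        for i, j in enumerate(causal):
            g = int(subgroup[i])
            z = rng.standard_normal(len(cols[g]))
            B[j, cols[g]] = chol[g] @ z
    return B, subgroup


def scale_to_pve(B_raw: np.ndarray, X: np.ndarray, spec: ScenarioSpec):
    """Rescale effect columns to hit per-condition PVE targets on realised X.

    For condition s with target ``pve_s``, the column is scaled so that
    ``Var(X b_s) = pve_s`` and the residual variance is ``1 - pve_s``, making
    the total variance of every condition equal to 1. Conditions with no
    effects keep residual variance 1.
    """
    targets = spec.pve_targets()
    B = B_raw.copy()
    r = spec.r
    G = X @ B
    gvar = G.var(axis=0, ddof=1)
    for s in range(r):
        if targets[s] > 0:
            if gvar[s] <= 0:
                raise ValueError(
                    f"condition {s + 1} has PVE target {targets[s]} but no "
                    "genetic variance to scale"
                )
            B[:, s] *= np.sqrt(targets[s] / gvar[s])
        else:
            B[:, s] = 0.0
    resid_var = 1.0 - targets
    D = np.sqrt(resid_var)
    corr = (1 - spec.resid_corr) * np.eye(r) + spec.resid_corr * np.ones((r, r))
    V_true = D[:, None] * corr * D[None, :]
    if spec.resid_corr == 0:
        V_true = np.diag(resid_var)
    return B, V_true


def apply_missingness(Y: np.ndarray, missing_rate: float, seed=0) -> np.ndarray:
    """Independent Bernoulli observation mask; rows losing every entry are redrawn."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = _rng(seed)
    n, r = Y.shape
    mask = rng.random((n, r)) >= missing_rate
    if missing_rate > 0:
        for i in range(n):
            while not mask[i].any():
                mask[i] = rng.random(r) >= missing_rate
    return mask


def _draw_noise(n: int, V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(V + 1e-15 * np.eye(V.shape[0]))
    return rng.standard_normal((n, V.shape[0])) @ L.T


def simulate_dataset(spec: ScenarioSpec) -> SimulatedDataset:
    """Generate a complete train/test dataset for the given scenario.

    Fully reproducible: identical specs produce identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n, spec.p
    X, mafs = simulate_genotypes(n, p, spec.maf_range, rng)
    causal = np.sort(rng.choice(p, size=spec.n_causal, replace=False))
    B_raw, subgroup = simulate_effects(spec, causal, rng)
    n_train = spec.n_train
    X_train, X_test = X[:n_train], X[n_train:]
    B_true, V_true = scale_to_pve(B_raw, X_train, spec)
    Y = X @ B_true + _draw_noise(n, V_true, rng)
    mask = apply_missingness(Y[:n_train], spec.missing_rate, rng)
    targets = spec.pve_targets()
    G = X_train @ B_true
    gvar = G.var(axis=0, ddof=1)
    pve_realized = gvar / (gvar + np.diag(V_true))
    Y_train = np.where(mask, Y[:n_train], np.nan)
    train = RegressionDataset(X_train, Y_train, mask)
    test = None
    if n > n_train:
        test = RegressionDataset(
            X_test,
            Y[n_train:],
            sample_ids=[f"t{i + 1:04d}" for i in range(n - n_train)],
        )
    assert np.allclose(pve_realized, targets, atol=1e-10)
    return SimulatedDataset(
        train=train,
        test=test,
        B_true=B_true,
        V_true=V_true,
        causal_indices=causal,
        pve_realized=pve_realized,
        mafs=mafs,
        spec=spec,
        causal_subgroup=subgroup,
    )


def replicate_samples(sim: SimulatedDataset, n_new: int, seed=0):
    """Fresh samples from the same generative truth (same MAFs, B, V).

    Useful for estimating population (out-of-sample) quantities such as the
    realised PVE with an arbitrarily large test draw.
    """
    rng = _rng(seed)
    X = rng.binomial(2, sim.mafs[None, :], size=(n_new, len(sim.mafs))).astype(float)
    Y = X @ sim.B_true + _draw_noise(n_new, sim.V_true, rng)
    return X, Y
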