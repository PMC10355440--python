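"""Construction of the prior covariance collection.

Two families of r x r effect-sharing patterns are supported: "canonical"
patterns written down a priori (independent effects, equal effects,
condition-specific effects, constant-correlation sharing), and "data-driven"
patterns estimated from the strongest univariate signals in the data
(empirical covariance of effect estimates plus leading rank-1 principal
components). Each base pattern is expanded across a grid of scales and
combined with a null (all-zeros) component into a mixture prior template.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mrmash.datasets import RegressionDataset
from mrmash.model_core import MixturePrior

#: Default grid of prior effect variances, relative to unit outcome variance.
DEFAULT_SCALE_GRID = (0.01, 0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6)


@dataclass(frozen=True)
class CovarianceRecipe:
    """How to build the prior covariance collection.

    ``n_strong`` is the number of strong-signal variables used for the
    data-driven estimate (default: 100 capped at p, but at least 2r);
    ``n_pcs`` the number of rank-1 principal-axis patterns (default
    ``min(3, r)``).
    """

    kind: str = "data_driven"
    scale_grid: tuple[float, ...] = DEFAULT_SCALE_GRID
    n_strong: int | None = None
    n_pcs: int | None = None
    include_null: bool = True
    z_floor: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("canonical", "data_driven", "both"):
            raise ValueError("kind must be 'canonical', 'data_driven' or 'both'")
        grid = tuple(float(s) for s in self.scale_grid)
        if not grid or any(s <= 0 for s in grid):
            raise ValueError("scale_grid must be non-empty and strictly positive")
        if list(grid) != sorted(grid):
            raise ValueError("scale_grid must be sorted ascending")
        object.__setattr__(self, "scale_grid", grid)

    def resolved_n_strong(self, p: int, r: int) -> int:
        n_strong = self.n_strong
        if n_strong is None:
            n_strong = max(2 * r, min(100, p))
        if n_strong < r:
            raise ValueError("n_strong must be at least r")
        return n_strong

    def resolved_n_pcs(self, r: int) -> int:
        n_pcs = min(3, r) if self.n_pcs is None else self.n_pcs
        if not 0 <= n_pcs <= r:
            raise ValueError("n_pcs must lie in [0, r]")
        return n_pcs


def canonical_covariances(r: int) -> tuple[list[np.ndarray], list[str]]:
    """Pre-specified effect-sharing patterns, unscaled and deduplicated.

    Returns the identity ("independent"), the all-ones matrix ("equal
    effects"), one singleton matrix per condition, and unit-diagonal matrices
    with constant off-diagonal correlation 0.25, 0.5 and 0.75.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    mats: list[np.ndarray] = [np.eye(r), np.ones((r, r))]
    labels = ["independent", "equal_effects"]
    for s in range(r):
        e = np.zeros((r, r))
        e[s, s] = 1.0
        mats.append(e)
        labels.append(f"singleton_{s + 1}")
    for rho in (0.25, 0.5, 0.75):
        mats.append((1.0 - rho) * np.eye(r) + rho * np.ones((r, r)))
        labels.append(f"shared_het_{rho}")
    return _dedupe(mats, labels)


def data_driven_covariances(
    data: RegressionDataset, recipe: CovarianceRecipe | None = None
) -> tuple[list[np.ndarray], list[str]]:
    """Effect-sharing patterns learned from strong univariate signals.

    Per variable and condition, a simple (single-predictor) regression on the
    observed entries yields an effect estimate and z-score. The ``n_strong``
    variables with largest max-abs z across conditions contribute their
    effect-estimate rows E (further restricted to rows whose max-abs z
    clears ``z_floor`` when at least three do, so that clear signals are not
    diluted by ranked-but-insignificant rows); the returned patterns are the
    uncentred empirical
    covariance E'E / n_strong — with the mean squared standard error
    subtracted from its diagonal (a method-of-moments debias) and eigenvalues
    clipped at zero — and the top ``n_pcs`` rank-1 outer products of its
    principal axes, each normalised to unit maximum diagonal.
    """
    recipe = recipe or CovarianceRecipe()
    X, Y, mask = data.X, data.Y, data.mask
    p, r = data.p, data.r
    bhat = np.zeros((p, r))
    zscore = np.zeros((p, r))
    se2 = np.zeros((p, r))
    for s in range(r):
        obs = mask[:, s]
        m = int(obs.sum())
        if m < 3:
            continue
        y = Y[obs, s]
        Xs = X[obs]
        xm = Xs.mean(axis=0)
        Xcent = Xs - xm
        ycent = y - y.mean()
        sxx = np.einsum("ij,ij->j", Xcent, Xcent)
        usable = sxx > 0
        sxy = ycent @ Xcent
        b = np.divide(sxy, sxx, out=np.zeros(p), where=usable)
        syy = float(ycent @ ycent)
        rss = np.maximum(syy - b * sxy, 0.0)
        sigma2 = rss / max(m - 2, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2 / sxx)
            z = np.where(usable & (se > 0), b / se, 0.0)
        bhat[:, s] = b
        zscore[:, s] = z
        se2[:, s] = np.where(usable, sigma2 / np.where(usable, sxx, 1.0), 0.0)
    usable_rows = np.flatnonzero(np.abs(zscore).max(axis=1) > 0)
    n_strong = recipe.resolved_n_strong(p, r)
    if usable_rows.size < n_strong:
        warnings.warn(
            f"only {usable_rows.size} usable variables for data-driven "
            f"covariances (requested {n_strong}); using all",
            stacklevel=2,
        )
        strong = usable_rows
    else:
        strength = np.abs(zscore).max(axis=1)
        strong = np.argsort(-strength, kind="stable")[:n_strong]
        significant = strong[strength[strong] >= recipe.z_floor]
        if len(significant) >= 3:
            strong = significant
    E = bhat[strong]
    mats: list[np.ndarray] = []
    labels: list[str] = []
    S_emp = E.T @ E / max(len(strong), 1)
    # debias: the diagonal of E'E/n carries the sampling variance of the
    # effect estimates; remove its average and clip back to PSD
    S_emp = S_emp - np.diag(se2[strong].mean(axis=0))
    eigval, eigvec = np.linalg.eigh(0.5 * (S_emp + S_emp.T))
    eigval = np.maximum(eigval, 0.0)
    S_emp = (eigvec * eigval) @ eigvec.T
    if np.diag(S_emp).max() > 0:
        mats.append(S_emp / np.diag(S_emp).max())
        labels.append("data_driven_cov")
    lam_floor = 0.05 * eigval.max() if eigval.max() > 0 else 0.0
    for i in range(min(recipe.resolved_n_pcs(r), len(eigval))):
        lam = eigval[::-1][i]
        if lam <= 0 or lam < lam_floor:
            break
        vec = eigvec[:, ::-1][:, i]
        mat = lam * np.outer(vec, vec)
        d = np.diag(mat).max()
        if d > 0:
            mats.append(mat / d)
            labels.append(f"data_driven_pc{i + 1}")
    if not mats:
        mats = [np.eye(r)]
        labels = ["data_driven_fallback_identity"]
    return _dedupe(mats, labels)


def _dedupe(mats, labels, tol: float = 1e-12):
    kept: list[np.ndarray] = []
    kept_labels: list[str] = []
    for mat, label in zip(mats, labels):
        mat = 0.5 * (mat + mat.T)
        if any(np.abs(mat - other).max() <= tol for other in kept):
            continue
        kept.append(mat)
        kept_labels.append(label)
    return kept, kept_labels


def expand_with_scale_grid(
    bases: list[np.ndarray],
    scale_grid=DEFAULT_SCALE_GRID,
    include_null: bool = True,
    base_labels: list[str] | None = None,
) -> MixturePrior:
    """Outer product of base patterns with a scale grid, as a mixture template.

    Deduplicates entrywise-equal matrices, prepends the null component when
    requested, and assigns uniform initial weights.
    """
    if not len(bases) or not len(scale_grid):
        raise ValueError("bases and scale_grid must be non-empty")
    r = np.asarray(bases[0]).shape[0]
    if base_labels is None:
        base_labels = [f"base_{i}" for i in range(len(bases))]
    mats: list[np.ndarray] = []
    labels: list[str] = []
    if include_null:
        mats.append(np.zeros((r, r)))
        labels.append("null")
    for base, label in zip(bases, base_labels):
        base = np.asarray(base, dtype=float)
        for scale in scale_grid:
            mats.append(scale * base)
            labels.append(f"{label},scale={scale:g}")
    mats, labels = _dedupe(mats, labels)
    K = len(mats)
    return MixturePrior(np.stack(mats), np.full(K, 1.0 / K), tuple(labels))


def build_prior(
    data: RegressionDataset, recipe: CovarianceRecipe | None = None
) -> MixturePrior:
    """Assemble the full prior template for a dataset per the recipe."""
    recipe = recipe or CovarianceRecipe()
    bases: list[np.ndarray] = []
    labels: list[str] = []
    if recipe.kind in ("canonical", "both"):
        m, l = canonical_covariances(data.r)
        bases += m
        labels += l
    if recipe.kind in ("data_driven", "both"):
        m, l = data_driven_covariances(data, recipe)
        bases += m
        labels += l
    bases, labels = _dedupe(bases, labels)
    return expand_with_scale_grid(
        bases, recipe.scale_grid, recipe.include_null, labels
    )


def save_covariances(
    directory: str | Path, mats: list[np.ndarray], labels: list[str]
) -> None:
    """Write a labelled covariance collection as delimited matrices + manifest."""
    from mrmash.io import write_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    r = np.asarray(mats[0]).shape[0]
    ids = [f"cond{s + 1:02d}" for s in range(r)]
    files = []
    for i, (mat, label) in enumerate(zip(mats, labels)):
        fname = f"cov_{i:03d}.tsv"
        write_matrix(directory / fname, np.asarray(mat), ids, ids)
        files.append({"file": fname, "label": label})
    (directory / "manifest.json").write_text(
        json.dumps({"format": "mrmash-covariances", "matrices": files}, indent=2)
        + "\n"
    )


def load_covariances(directory: str | Path):
    from mrmash.io import read_matrix

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    mats, labels = [], []
    for entry in manifest["matrices"]:
        mat, _, _ = read_matrix(directory / entry["file"])
        mats.append(mat)
        labels.append(entry["label"])
    return mats, labels
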