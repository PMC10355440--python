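"""Container for a multivariate regression dataset with partially observed outcomes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _default_ids(prefix: str, k: int) -> list[str]:
    width = max(4, len(str(k)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(k)]


@dataclass
class RegressionDataset:
    """Predictors ``X`` (n x p), outcomes ``Y`` (n x r) and an observation mask.

    ``mask[i, s]`` is True where outcome ``s`` was observed for sample ``i``.
    If ``mask`` is omitted it is derived from NaN entries in ``Y``. ``X`` must
    be fully observed. Constant predictor columns are permitted but flagged
    through :attr:`constant_predictors`; downstream fitting refuses to use
    them rather than silently producing NaNs.
    """

    X: np.ndarray
    Y: np.ndarray
    mask: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    predictor_ids: list[str] = field(default_factory=list)
    condition_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D matrices")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} samples but Y has {self.Y.shape[0]}"
            )
        if np.isnan(self.X).any():
            i, j = np.argwhere(np.isnan(self.X))[0]
            raise ValueError(f"X contains a missing value at row {i}, column {j}")
        if self.mask is None:
            self.mask = ~np.isnan(self.Y)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.Y.shape:
                raise ValueError("mask shape must match Y")
            if np.isnan(self.Y[self.mask]).any():
                raise ValueError("Y contains NaN at entries marked observed")
        n, p = self.X.shape
        r = self.Y.shape[1]
        if not self.sample_ids:
            self.sample_ids = _default_ids("s", n)
        if not self.predictor_ids:
            self.predictor_ids = _default_ids("v", p)
        if not self.condition_ids:
            self.condition_ids = _default_ids("cond", r)
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match X rows")
        if len(self.predictor_ids) != p:
            raise ValueError("predictor_ids length does not match X columns")
        if len(self.condition_ids) != r:
            raise ValueError("condition_ids length does not match Y columns")
        rows_obs = self.mask.sum(axis=1)
        if (rows_obs == 0).any():
            i = int(np.argmin(rows_obs))
            raise ValueError(f"sample {self.sample_ids[i]} has no observed outcome")
        cols_obs = self.mask.sum(axis=0)
        if (cols_obs < 2).any():
            s = int(np.argmin(cols_obs))
            raise ValueError(
                f"condition {self.condition_ids[s]} has fewer than two observed outcomes"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def r(self) -> int:
        return self.Y.shape[1]

    @property
    def constant_predictors(self) -> np.ndarray:
        """Boolean flag per predictor column: True where the column is constant."""
        return np.ptp(self.X, axis=0) == 0

    def observed_values(self, condition: int) -> np.ndarray:
        """Observed outcome values for one condition."""
        return self.Y[self.mask[:, condition], condition]
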