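"""Longitudinal data container: typed covariates, missingness flags,
standardisation and subject-wise indexing.

A dataset is a table with one row per (subject, visit): a subject identifier,
covariates that are continuous (age, time from a disease event, season),
binary (group, gender, location) or categorical (subject id), and one numeric
target.  Missing covariate values are recorded in per-covariate 0/1 flag
vectors and are never imputed — the kernel machinery masks them out instead.

Continuous covariates feeding a non-stationary kernel are passed through the
sigmoid warp (on the raw time scale, in months) when the dataset is built;
standardisation then treats the warped coordinate like any other continuous
covariate, so the effective event window is set in month units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import DEFAULT_WARP, sigmoid_warp

__all__ = ["Covariate", "LongitudinalDataset", "StandardisationRecord"]

_KINDS = ("continuous", "binary", "categorical")
_DEFAULT_KERNEL = {"continuous": "se", "binary": "bi", "categorical": "ca"}
_VALID_KERNELS = {"continuous": ("se", "periodic", "ns"), "binary": ("bi",), "categorical": ("ca",)}


@dataclass(frozen=True)
class Covariate:
    """Declaration of one covariate column.

    ``interactions`` ('allowed'/'forbidden') feeds the default interaction
    rule of the forward search; ``period`` (periodic kernel) and ``warp``
    (non-stationary kernel, constants a, b, c) are fixed, user-set values.
    """

    name: str
    kind: str
    kernel: str = ""
    interactions: str = "allowed"
    period: float | None = None
    warp: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"covariate {self.name}: unknown kind {self.kind!r}")
        kernel = self.kernel or _DEFAULT_KERNEL[self.kind]
        object.__setattr__(self, "kernel", kernel)
        if kernel not in _VALID_KERNELS[self.kind]:
            raise ValueError(f"covariate {self.name}: kernel {kernel!r} invalid for kind {self.kind!r}")
        if kernel == "periodic" and not (self.period and self.period > 0):
            raise ValueError(f"covariate {self.name}: periodic kernel needs a positive period")
        if self.interactions not in ("allowed", "forbidden"):
            raise ValueError(f"covariate {self.name}: interactions must be 'allowed' or 'forbidden'")
        if kernel == "ns" and self.warp is None:
            object.__setattr__(self, "warp", DEFAULT_WARP)


@dataclass(frozen=True)
class StandardisationRecord:
    """Column means/standard deviations (observed entries, sample sd) for the
    target and each standardised continuous covariate; supports the exact
    back-transform of predictions to the original target scale."""

    column_stats: dict[str, tuple[float, float]]
    target_stats: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (_, sd) in {**self.column_stats, "__target__": self.target_stats}.items():
            if not sd > 0:
                raise ValueError(f"standardisation sd for {name} must be positive")

    def forward_target(self, y):
        mean, sd = self.target_stats
        return (np.asarray(y, dtype=float) - mean) / sd

    def inverse_target(self, y_std):
        mean, sd = self.target_stats
        return np.asarray(y_std, dtype=float) * sd + mean

    def inverse_component_mean(self, mu_std):
        """Component means are zero-mean on the standardised scale; only the
        scale (not the offset) is restored."""
        _, sd = self.target_stats
        return np.asarray(mu_std, dtype=float) * sd

    def inverse_variance(self, var_std):
        _, sd = self.target_stats
        return np.asarray(var_std, dtype=float) * sd**2


class LongitudinalDataset:
    """N samples x d typed covariates plus a numeric target, grouped by subject."""

    def __init__(self, covariates, X, flags, y, subject_labels, level_maps=None) -> None:
        self.covariates: dict[str, Covariate] = {c.name: c for c in covariates}
        self.X = np.asarray(X, dtype=float)
        self.flags = np.asarray(flags, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.subject_labels = np.asarray(subject_labels)
        self.level_maps: dict[str, list] = level_maps or {}
        n, d = self.X.shape
        if len(self.y) != n or self.flags.shape != (n, d) or len(self.subject_labels) != n:
            raise ValueError("inconsistent dataset shapes")
        if not np.isin(self.flags, (0.0, 1.0)).all():
            raise ValueError("missingness flags must be exactly 0 or 1")
        if np.any(np.isnan(self.X) & (self.flags == 1.0)):
            raise ValueError("flag 1 on a missing covariate value")
        self._index = {name: i for i, name in enumerate(self.covariates)}
        # subjects in first-appearance order
        _, first = np.unique(self.subject_labels, return_index=True)
        self.subjects = [self.subject_labels[i] for i in sorted(first)]
        self._subject_rows = {
            s: np.flatnonzero(self.subject_labels == s) for s in self.subjects
        }

    # -- basic accessors ----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def declaration(self, name: str) -> Covariate:
        return self.covariates[name]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self._index[name]]

    def flag(self, name: str) -> np.ndarray:
        return self.flags[:, self._index[name]]

    def subject_rows(self, subject) -> np.ndarray:
        if subject not in self._subject_rows:
            raise KeyError(f"unknown subject {subject!r}")
        return self._subject_rows[subject]

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates, target: str, subject: str) -> "LongitudinalDataset":
        """Build a dataset from a DataFrame given covariate declarations.

        Empty cells and the literals NA/NaN count as missing.  Categorical
        levels are coded in first-appearance order; a categorical covariate
        whose name equals the subject column reuses the subject labels.
        """
        covariates = list(covariates)
        missing_cols = [c.name for c in covariates if c.name not in df.columns]
        if target not in df.columns:
            missing_cols.append(target)
        if subject not in df.columns:
            missing_cols.append(subject)
        if missing_cols:
            raise KeyError(f"declared columns missing from table: {missing_cols}")
        if df[subject].isna().any():
            raise ValueError("every row must have a subject identifier")

        y_raw = pd.to_numeric(df[target], errors="coerce")
        bad = np.flatnonzero(y_raw.isna().to_numpy())
        if bad.size:
            raise ValueError(f"non-numeric or missing target value at row {bad[0]}")

        n = len(df)
        X = np.full((n, len(covariates)), np.nan)
        flags = np.zeros((n, len(covariates)))
        level_maps: dict[str, list] = {}
        for k, cov in enumerate(covariates):
            raw = df[cov.name]
            if cov.kind == "categorical":
                observed = ~raw.isna().to_numpy()
                levels: list = []
                codes = np.full(n, np.nan)
                seen: dict = {}
                for i, v in enumerate(raw):
                    if not observed[i]:
                        continue
                    if v not in seen:
                        seen[v] = len(levels)
                        levels.append(v)
                    codes[i] = seen[v]
                X[:, k] = codes
                level_maps[cov.name] = levels
                flags[:, k] = observed.astype(float)
            else:
                vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
                observed = ~np.isnan(vals)
                if cov.kind == "binary" and not np.isin(vals[observed], (0.0, 1.0)).all():
                    raise ValueError(f"binary covariate {cov.name} has values outside {{0, 1}}")
                if cov.kernel == "ns":
                    a, b, c_ = cov.warp
                    vals = np.where(observed, sigmoid_warp(np.nan_to_num(vals), a, b, c_), np.nan)
                X[:, k] = vals
                flags[:, k] = observed.astype(float)
        return cls(covariates, X, flags, y_raw.to_numpy(dtype=float), df[subject].to_numpy(), level_maps)

    @classmethod
    def load_table(cls, path, covariates, target: str, subject: str) -> "LongitudinalDataset":
        """Read a delimited text table (comma or tab separated, header row)."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep)
        return cls.from_frame(df, covariates, target, subject)

    # -- transforms ---------------------------------------------------------

    def standardise(self, include_target: bool = True) -> tuple["LongitudinalDataset", StandardisationRecord]:
        """Z-score the target and the non-periodic continuous covariates.

        Statistics use observed entries only (sample sd); missing entries are
        untouched.  Periodic covariates keep their natural units so the
        user-set period stays meaningful.  A constant column is fatal.
        With ``include_target=False`` only the covariates are transformed
        (used by the simulator, where the target does not exist yet).
        """
        X = self.X.copy()
        stats: dict[str, tuple[float, float]] = {}
        for name, cov in self.covariates.items():
            if cov.kind != "continuous" or cov.kernel == "periodic":
                continue
            k = self._index[name]
            obs = self.flags[:, k] == 1.0
            if not obs.any():
                continue
            mean = float(np.mean(X[obs, k]))
            sd = float(np.std(X[obs, k], ddof=1)) if obs.sum() > 1 else 0.0
            if sd <= 0:
                raise ValueError(f"cannot standardise constant column {name!r}")
            X[obs, k] = (X[obs, k] - mean) / sd
            stats[name] = (mean, sd)
        if include_target:
            y_mean = float(np.mean(self.y))
            y_sd = float(np.std(self.y, ddof=1))
            if y_sd <= 0:
                raise ValueError("cannot standardise constant target")
            y = (self.y - y_mean) / y_sd
        else:
            y_mean, y_sd = 0.0, 1.0
            y = self.y
        record = StandardisationRecord(stats, (y_mean, y_sd))
        ds = LongitudinalDataset(
            list(self.covariates.values()), X, self.flags, y,
            self.subject_labels, self.level_maps,
        )
        return ds, record

    def subject_partition(self, subject) -> tuple[np.ndarray, np.ndarray]:
        """Leave-one-subject-out split: (training rows, the subject's rows)."""
        test = self.subject_rows(subject)
        mask = np.ones(self.n_rows, dtype=bool)
        mask[test] = False
        return np.flatnonzero(mask), test

    def subset(self, rows) -> "LongitudinalDataset":
        rows = np.asarray(rows)
        return LongitudinalDataset(
            list(self.covariates.values()), self.X[rows], self.flags[rows],
            self.y[rows], self.subject_labels[rows], self.level_maps,
        )

    def to_frame(self, target: str = "y", subject: str = "id") -> pd.DataFrame:
        """Back to a table with original categorical labels.

        Continuous columns are returned as stored — i.e. warped for
        non-stationary covariates, and standardised if ``standardise`` has
        been applied."""
        out = {}
        if subject not in self.covariates:
            out[subject] = self.subject_labels
        for name, cov in self.covariates.items():
            col = self.column(name)
            if cov.kind == "categorical":
                levels = self.level_maps.get(name)
                vals = [
                    levels[int(c)] if levels is not None and not np.isnan(c) else (np.nan if np.isnan(c) else int(c))
                    for c in col
                ]
                out[name] = vals
            else:
                out[name] = col
        out[target] = self.y
        return pd.DataFrame(out)
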