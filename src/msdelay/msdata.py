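"""Core record types for illness-death treatment-delay data.

The observational unit is a subject who starts untreated (state 1) and may
move to treatment (state 2) and/or recovery (state 3).  Each subject carries

* ``w`` / ``delta_w`` — time and type of the *first* event on the study clock:
  ``delta_w = 1`` treatment initiation, ``delta_w = 2`` recovery without
  treatment, ``delta_w = 0`` censored before either;
* ``r`` / ``delta_r`` — observed recovery/censoring time and recovery status.

Times are in abstract study units (the motivating application uses years, so
0.25 corresponds to "3 months").  All baseline covariates are assumed complete;
rows with missing covariate values are rejected rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NEVER",
    "Subject",
    "Strategy",
    "IllnessDeathDataset",
    "FormatError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "validate",
]

#: Distinguished delay value for the "never initiate treatment" strategy.
NEVER = math.inf


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected schema."""


class ValidationError(ValueError):
    """Raised when subject records violate the illness-death invariants."""


@dataclass(frozen=True)
class Subject:
    """One observational unit of the illness-death process."""

    id: str
    x: tuple[float, ...]
    w: float
    delta_w: int
    r: float
    delta_r: int

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        out: list[str] = []
        if not (0.0 <= self.w):
            out.append(f"subject {self.id}: w={self.w} is negative")
        if self.w > self.r:
            out.append(f"subject {self.id}: r={self.r} < w={self.w}")
        if self.delta_w not in (0, 1, 2):
            out.append(f"subject {self.id}: delta_w={self.delta_w} not in {{0,1,2}}")
        if self.delta_r not in (0, 1):
            out.append(f"subject {self.id}: delta_r={self.delta_r} not in {{0,1}}")
        if self.delta_w == 2 and not (self.r == self.w and self.delta_r == 1):
            out.append(
                f"subject {self.id}: untreated recovery requires r == w and "
                f"delta_r == 1 (got r={self.r}, w={self.w}, delta_r={self.delta_r})"
            )
        if self.delta_w == 0 and not (self.r == self.w and self.delta_r == 0):
            out.append(
                f"subject {self.id}: censoring before first event requires "
                f"r == w and delta_r == 0 (got r={self.r}, w={self.w}, "
                f"delta_r={self.delta_r})"
            )
        if any(not math.isfinite(v) for v in self.x):
            out.append(f"subject {self.id}: non-finite covariate value")
        if not (math.isfinite(self.w) and math.isfinite(self.r)):
            out.append(f"subject {self.id}: non-finite event time")
        return out


@dataclass(frozen=True)
class Strategy:
    """Treatment-delay rule "initiate at ``tg`` if not yet recovered".

    ``tg = NEVER`` (infinity) encodes never initiating during follow-up.
    ``grace_halfwidth`` widens the rule to "initiate within
    [tg - h, tg + h)" (clipped at 0), which is the grace-window form used
    when treatment times are continuous; the never strategy admits no grace.
    """

    tg: float
    grace_halfwidth: float = 0.0

    def __post_init__(self) -> None:
        if self.tg < 0:
            raise ValueError("strategy delay must be nonnegative")
        if self.grace_halfwidth < 0:
            raise ValueError("grace half-width must be nonnegative")
        if self.is_never and self.grace_halfwidth > 0:
            raise ValueError("the never strategy admits no grace window")

    @property
    def is_never(self) -> bool:
        return math.isinf(self.tg)

    @property
    def window(self) -> tuple[float, float]:
        """Adherence window [a, b) on the study clock (a == b for a point rule)."""
        if self.is_never:
            return (math.inf, math.inf)
        a = max(0.0, self.tg - self.grace_halfwidth)
        b = self.tg + self.grace_halfwidth
        return (a, b)

    @classmethod
    def never(cls) -> "Strategy":
        return cls(tg=NEVER)

    def label(self) -> str:
        if self.is_never:
            return "never"
        if self.grace_halfwidth > 0:
            a, b = self.window
            return f"{self.tg:g}[{a:g},{b:g})"
        return f"{self.tg:g}"


_RESERVED = ("id", "w", "delta_w", "r", "delta_r")


@dataclass
class IllnessDeathDataset:
    """A validated collection of subjects with a shared covariate layout.

    The canonical in-memory form is a :class:`pandas.DataFrame` with columns
    ``id, <covariates...>, w, delta_w, r, delta_r`` (row order preserved).
    """

    frame: pd.DataFrame
    covariate_names: list[str]
    horizon: float = 1.5

    def __post_init__(self) -> None:
        missing = [c for c in (*_RESERVED, *self.covariate_names) if c not in self.frame.columns]
        if missing:
            raise FormatError(f"dataset frame is missing columns: {missing}")
        ordered = ["id", *self.covariate_names, "w", "delta_w", "r", "delta_r"]
        self.frame = self.frame.loc[:, ordered].reset_index(drop=True)
        self.frame["id"] = self.frame["id"].astype(str)
        for c in (*self.covariate_names, "w", "r"):
            self.frame[c] = pd.to_numeric(self.frame[c], errors="coerce").astype(float)
        for c in ("delta_w", "delta_r"):
            # tolerate float-encoded status columns as written by other tools
            vals = pd.to_numeric(self.frame[c], errors="coerce")
            self.frame[c] = vals.fillna(-1).astype(int)

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def x(self) -> np.ndarray:
        """Baseline covariates as an (n, p) array."""
        return self.frame[self.covariate_names].to_numpy(dtype=float)

    @property
    def w(self) -> np.ndarray:
        return self.frame["w"].to_numpy(dtype=float)

    @property
    def delta_w(self) -> np.ndarray:
        return self.frame["delta_w"].to_numpy(dtype=int)

    @property
    def r(self) -> np.ndarray:
        return self.frame["r"].to_numpy(dtype=float)

    @property
    def delta_r(self) -> np.ndarray:
        return self.frame["delta_r"].to_numpy(dtype=int)

    def subjects(self) -> Iterable[Subject]:
        p = self.covariate_names
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            yield Subject(
                id=str(d["id"]),
                x=tuple(float(d[c]) for c in p),
                w=float(d["w"]),
                delta_w=int(d["delta_w"]),
                r=float(d["r"]),
                delta_r=int(d["delta_r"]),
            )

    def equals(self, other: "IllnessDeathDataset") -> bool:
        if self.covariate_names != other.covariate_names:
            return False
        a, b = self.frame, other.frame
        if a.shape != b.shape:
            return False
        if not (a["id"].tolist() == b["id"].tolist()):
            return False
        num = [*self.covariate_names, "w", "r"]
        return bool(
            np.allclose(a[num].to_numpy(), b[num].to_numpy(), rtol=0, atol=1e-12)
            and (a[["delta_w", "delta_r"]].to_numpy() == b[["delta_w", "delta_r"]].to_numpy()).all()
        )

    @classmethod
    def from_arrays(
        cls,
        x: np.ndarray,
        w: np.ndarray,
        delta_w: np.ndarray,
        r: np.ndarray,
        delta_r: np.ndarray,
        covariate_names: Sequence[str] | None = None,
        ids: Sequence[str] | None = None,
        horizon: float = 1.5,
    ) -> "IllnessDeathDataset":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] != len(w):
            x = x.T
        p = x.shape[1]
        names = list(covariate_names) if covariate_names is not None else [f"x{j}" for j in range(p)] if p != 1 else ["x"]
        frame = pd.DataFrame({"id": ids if ids is not None else [str(i) for i in range(len(w))]})
        for j, name in enumerate(names):
            frame[name] = x[:, j]
        frame["w"] = np.asarray(w, dtype=float)
        frame["delta_w"] = np.asarray(delta_w, dtype=int)
        frame["r"] = np.asarray(r, dtype=float)
        frame["delta_r"] = np.asarray(delta_r, dtype=int)
        return cls(frame=frame, covariate_names=names, horizon=horizon)


def validate(dataset: IllnessDeathDataset) -> list[str]:
    """Report all invariant violations; total (never raises on bad content)."""
    out: list[str] = []
    f = dataset.frame
    ids = f["id"].to_numpy()
    w, r = dataset.w, dataset.r
    dw, dr = dataset.delta_w, dataset.delta_r
    x = dataset.x

    def flag(mask: np.ndarray, msg: str) -> None:
        for i in np.flatnonzero(mask):
            out.append(f"subject {ids[i]}: {msg}")

    flag(~np.isfinite(w) | ~np.isfinite(r), "non-finite event time")
    ok = np.isfinite(w) & np.isfinite(r)
    flag(ok & (w < 0), "w is negative")
    flag(ok & (r < w), "r < w")
    flag(~np.isin(dw, [0, 1, 2]), "delta_w not in {0,1,2}")
    flag(~np.isin(dr, [0, 1]), "delta_r not in {0,1}")
    flag(ok & (dw == 2) & ~((r == w) & (dr == 1)), "untreated recovery requires r == w and delta_r == 1")
    flag(ok & (dw == 0) & ~((r == w) & (dr == 0)), "censoring before first event requires r == w and delta_r == 0")
    flag(~np.isfinite(x).all(axis=1), "missing or non-finite covariate value")
    return out


def truncate_follow_up(dataset: IllnessDeathDataset, horizon: float | None = None) -> IllnessDeathDataset:
    """Administratively censor all follow-up at the horizon.

    Subjects whose first event falls after the horizon become censored at the
    horizon; recoveries after the horizon become censored there as well.
    """
    h = dataset.horizon if horizon is None else float(horizon)
    f = dataset.frame.copy()
    w = f["w"].to_numpy(float)
    r = f["r"].to_numpy(float)
    dw = f["delta_w"].to_numpy(int)
    dr = f["delta_r"].to_numpy(int)
    late_first = w > h
    f.loc[late_first, ["w", "r"]] = h
    f.loc[late_first, ["delta_w", "delta_r"]] = 0
    late_rec = ~late_first & (r > h)
    f.loc[late_rec, "r"] = h
    f.loc[late_rec, "delta_r"] = 0
    return IllnessDeathDataset(frame=f, covariate_names=dataset.covariate_names, horizon=h)


def read_dataset(
    path, covariate_names: Sequence[str], horizon: float = 1.5
) -> IllnessDeathDataset:
    """Read a comma-separated subject table and validate it.

    The header must contain ``id``, the covariate columns, ``w``, ``delta_w``,
    ``r`` and ``delta_r``; extra columns are ignored.
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in (*_RESERVED, *covariate_names) if c not in frame.columns]
    if missing:
        raise FormatError(f"{path} is missing required columns: {missing}")
    ds = IllnessDeathDataset(frame=frame, covariate_names=list(covariate_names), horizon=horizon)
    problems = validate(ds)
    if problems:
        raise ValidationError("; ".join(problems[:20]))
    return ds


def write_dataset(dataset: IllnessDeathDataset, path) -> None:
    """Write the dataset as comma-separated text with a deterministic column order."""
    dataset.frame.to_csv(path, index=False)
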