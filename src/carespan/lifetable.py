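"""Period life tables from age-specific annual death rates.

Single-year-of-age tables with an open final interval.  Two conversions from
the central rate ``mx`` to the death probability ``qx`` are provided:

* ``exponential`` (default): ``qx = 1 - exp(-mx)``, person-years
  ``Lx = dx / mx``.  Exact when the hazard is constant within each interval —
  the natural companion of a fitted exponential hazard model.  A useful
  consequence: a schedule with constant rate ``m`` at every age (including
  closure) has ``ex = 1/m`` exactly.
* ``chiang``: ``qx = mx / (1 + 0.5 mx)`` with ``ax = 0.5``,
  ``Lx = l(x+1) + 0.5 dx`` — the textbook actuarial convention.

The open interval is always closed with ``q = 1`` and ``L = l / m``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rates import RateSchedule

_CONVERSIONS = ("exponential", "chiang")

_COLUMNS = ("age", "mx", "qx", "lx", "dx", "Lx", "Tx", "ex")


def ex_curve(m: np.ndarray, conversion: str = "exponential") -> np.ndarray:
    """Remaining life expectancy at each age of a rate schedule.

    Vectorised over leading dimensions: ``m`` of shape ``(..., A)`` yields
    ``ex`` of shape ``(..., A)``.  The last age is the open interval.
    """
    m = np.asarray(m, dtype=float)
    if m.shape[-1] < 2:
        raise ValueError("need at least two ages (closed + open interval)")
    if np.any(m <= 0):
        raise ValueError("all rates must be positive")
    m_closed = m[..., :-1]
    if conversion == "exponential":
        q = -np.expm1(-m_closed)
    elif conversion == "chiang":
        q = m_closed / (1.0 + 0.5 * m_closed)
    else:
        raise ValueError(f"conversion must be one of {_CONVERSIONS}")
    surv = np.cumprod(1.0 - q, axis=-1)
    ones = np.ones(m.shape[:-1] + (1,))
    l = np.concatenate([ones, surv], axis=-1)  # radix 1
    d = l[..., :-1] * q
    if conversion == "exponential":
        L_closed = d / m_closed
    else:
        L_closed = l[..., 1:] + 0.5 * d
    L_open = l[..., -1:] / m[..., -1:]
    L = np.concatenate([L_closed, L_open], axis=-1)
    T = np.cumsum(L[..., ::-1], axis=-1)[..., ::-1]
    return T / l


@dataclass
class LifeTable:
    """A complete period life table with standard columns."""

    ages: np.ndarray
    mx: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray
    radix: float
    conversion: str
    access: str = ""
    stratum: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c if c != "age" else "ages") for c in _COLUMNS})
        return df

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["radix"] = self.radix
        df["conversion"] = self.conversion
        df["access"] = self.access
        df["stratum"] = self.stratum
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(
            ages=df["age"].to_numpy(),
            mx=df["mx"].to_numpy(),
            qx=df["qx"].to_numpy(),
            lx=df["lx"].to_numpy(),
            dx=df["dx"].to_numpy(),
            Lx=df["Lx"].to_numpy(),
            Tx=df["Tx"].to_numpy(),
            ex=df["ex"].to_numpy(),
            radix=float(df["radix"].iloc[0]),
            conversion=str(df["conversion"].iloc[0]),
            access=str(df["access"].iloc[0]) if df["access"].notna().any() else "",
            stratum=str(df["stratum"].iloc[0]) if df["stratum"].notna().any() else "",
        )


def build_life_table(
    schedule: RateSchedule,
    conversion: str = "exponential",
    radix: float = 100_000.0,
) -> LifeTable:
    """Construct the full life table from an annual rate schedule.

    The last age of the schedule is treated as the open age interval
    (``q = 1``, ``L = l/m``); all earlier ages are single-year closed
    intervals.
    """
    m = np.asarray(schedule.m, float)
    ages = np.asarray(schedule.ages, int)
    if len(m) < 2:
        raise ValueError("schedule must cover at least two ages")
    if np.any(m <= 0):
        raise ValueError("all rates must be positive")
    if conversion not in _CONVERSIONS:
        raise ValueError(f"conversion must be one of {_CONVERSIONS}")

    m_closed = m[:-1]
    if conversion == "exponential":
        q_closed = -np.expm1(-m_closed)
    else:
        q_closed = m_closed / (1.0 + 0.5 * m_closed)
    qx = np.append(q_closed, 1.0)

    l_rel = np.concatenate([[1.0], np.cumprod(1.0 - q_closed)])
    lx = radix * l_rel
    dx = np.append(lx[:-1] - lx[1:], lx[-1])
    if conversion == "exponential":
        L_closed = dx[:-1] / m_closed
    else:
        L_closed = lx[1:] + 0.5 * dx[:-1]
    Lx = np.append(L_closed, lx[-1] / m[-1])
    Tx = np.cumsum(Lx[::-1])[::-1]
    # lx can underflow to 0 under extreme rates; leave ex = 0 there
    ex = np.divide(Tx, lx, out=np.zeros_like(Tx), where=lx > 0)
    return LifeTable(
        ages=ages, mx=m, qx=qx, lx=lx, dx=dx, Lx=Lx, Tx=Tx, ex=ex,
        radix=radix, conversion=conversion,
        access=schedule.access, stratum=schedule.stratum,
    )


def life_expectancy_at(table: LifeTable, age: int) -> float:
    """Remaining life expectancy ``ex`` at an exact age on the table's grid."""
    idx = np.flatnonzero(table.ages == age)
    if len(idx) == 0:
        raise ValueError(
            f"age {age} not in the life-table grid "
            f"[{table.ages.min()}..{table.ages.max()}]"
        )
    return float(table.ex[idx[0]])
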