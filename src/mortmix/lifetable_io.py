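"""HMD-dialect I/O, period life tables, and the synthetic count generator.

Reads "Deaths_1x1" / "Exposures_1x1" plain-text files in the Human Mortality
Database layout (two header lines, then whitespace-separated columns
``Year Age Female Male Total`` with a terminal "110+" age and "." for
missing), builds period life tables by the standard single-decrement
recursions, extracts the normalized death distribution d_x the mixture model
fits, and generates multinomial synthetic death counts from a known
parameter vector — the statistical structure the estimator assumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import DeathCounts
from .mixture import AgeGrid, DirectParams, bin_probabilities

__all__ = [
    "HMDFormatError",
    "MissingAgesError",
    "NegativeValueError",
    "RawVitalRecords",
    "read_hmd_1x1",
    "write_hmd_1x1",
    "load_vital_records",
    "build_life_table",
    "deaths_distribution",
    "simulate_death_counts",
]

OPEN_AGE = 110
_SEX_COLUMNS = {"f": "Female", "m": "Male", "total": "Total"}


class HMDFormatError(ValueError):
    """The file does not follow the HMD 1x1 layout."""


class MissingAgesError(HMDFormatError):
    """A year does not carry the complete age range 0..110+."""


class NegativeValueError(HMDFormatError):
    """A count or exposure is negative."""


@dataclass(frozen=True)
class RawVitalRecords:
    """Single-sex deaths and exposures by year and single age.

    ``data`` has columns year, age, deaths, exposure; age 110 denotes the
    open 110+ interval.  Either deaths or exposure may be NaN where the
    source file held ".".
    """

    data: pd.DataFrame
    sex: str

    def __post_init__(self) -> None:
        required = {"year", "age", "deaths", "exposure"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"records need columns {sorted(required)}")

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def for_year(self, year: int) -> pd.DataFrame:
        sub = self.data[self.data["year"] == year].sort_values("age")
        if len(sub) != OPEN_AGE + 1:
            raise MissingAgesError(f"year {year}: expected {OPEN_AGE + 1} ages, got {len(sub)}")
        return sub.reset_index(drop=True)


def _parse_age(token: str) -> int:
    if token.endswith("+"):
        token = token[:-1]
    try:
        return int(token)
    except ValueError as exc:
        raise HMDFormatError(f"unparseable age {token!r}") from exc


def read_hmd_1x1(path, sex: str = "m", years: tuple[int, int] | None = None) -> pd.DataFrame:
    """Read one value column of an HMD 1x1 file.

    Returns a tidy frame with columns ``year, age, value`` for the requested
    sex ("m", "f" or "total"); "110+" maps to age 110 and "." to NaN.
    Raises :class:`HMDFormatError` for a malformed header,
    :class:`MissingAgesError` for incomplete age ranges and
    :class:`NegativeValueError` for negative values.
    """
    if sex not in _SEX_COLUMNS:
        raise ValueError(f"sex must be one of {sorted(_SEX_COLUMNS)}, got {sex!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines[:5]):
        if line.split()[:2] == ["Year", "Age"]:
            header_idx = i
            break
    if header_idx is None:
        raise HMDFormatError("no 'Year Age ...' header found in the first lines")
    header = lines[header_idx].split()
    if header != ["Year", "Age", "Female", "Male", "Total"]:
        raise HMDFormatError(f"unexpected column header {header}")

    df = pd.read_csv(
        io.StringIO("\n".join(lines[header_idx:])),
        sep=r"\s+",
        na_values=["."],
        dtype={"Year": int, "Age": str},
    )
    df["Age"] = df["Age"].map(_parse_age)
    out = df.rename(columns={"Year": "year", "Age": "age"})[
        ["year", "age", _SEX_COLUMNS[sex]]
    ].rename(columns={_SEX_COLUMNS[sex]: "value"})
    if years is not None:
        lo, hi = years
        out = out[(out["year"] >= lo) & (out["year"] <= hi)]
        if out.empty:
            raise ValueError(f"no records in year range {years}")
    for year, sub in out.groupby("year"):
        ages = set(sub["age"])
        if ages != set(range(OPEN_AGE + 1)):
            raise MissingAgesError(f"year {year}: ages 0..{OPEN_AGE}+ incomplete")
    if (out["value"].dropna() < 0).any():
        raise NegativeValueError("negative counts present")
    return out.reset_index(drop=True)


def write_hmd_1x1(path, df: pd.DataFrame, description: str = "Synthetic, Deaths (period 1x1)") -> None:
    """Write a frame with columns year, age, female, male, total in the HMD
    1x1 layout (used for fixtures and round-trip tests)."""
    with open(path, "w") as fh:
        fh.write(description + "\n\n")
        fh.write(f"{'Year':>6}{'Age':>14}{'Female':>17}{'Male':>16}{'Total':>16}\n")
        for _, row in df.iterrows():
            age = int(row["age"])
            age_s = f"{age}+" if age == OPEN_AGE else str(age)
            fh.write(
                f"{int(row['year']):>6}{age_s:>14}"
                f"{row['female']:>17.2f}{row['male']:>16.2f}{row['total']:>16.2f}\n"
            )


def load_vital_records(
    deaths_path, exposures_path, sex: str = "m", years: tuple[int, int] | None = None
) -> RawVitalRecords:
    """Read matching Deaths_1x1 and Exposures_1x1 files into one record set."""
    d = read_hmd_1x1(deaths_path, sex=sex, years=years).rename(columns={"value": "deaths"})
    e = read_hmd_1x1(exposures_path, sex=sex, years=years).rename(columns={"value": "exposure"})
    merged = d.merge(e, on=["year", "age"], how="inner")
    return RawVitalRecords(data=merged, sex=sex)


# --- life table construction ---------------------------------------------

# Andreev-Kingkade piecewise coefficients for a0 as a function of m0
# (current HMD protocol); rows are (m0 threshold, intercept, slope).
_AK_MALE = ((0.02300, 0.14929, -1.99545), (0.08307, 0.02832, 3.26201), (np.inf, 0.29915, 0.0))
_AK_FEMALE = ((0.01724, 0.14903, -2.05527), (0.06891, 0.04667, 3.88089), (np.inf, 0.31411, 0.0))


def _a0_andreev_kingkade(m0: float, sex: str) -> float:
    def one(table):
        for threshold, intercept, slope in table:
            if m0 < threshold:
                return intercept + slope * m0
        return table[-1][1]

    if sex == "m":
        return one(_AK_MALE)
    if sex == "f":
        return one(_AK_FEMALE)
    return 0.5 * (one(_AK_MALE) + one(_AK_FEMALE))


def build_life_table(
    records: RawVitalRecords,
    year: int,
    *,
    a0_rule: str = "andreev-kingkade",
    radix: float = 100_000.0,
) -> pd.DataFrame:
    """Period life table for one year by the standard recursions.

    m_x = deaths/exposure; q_x = m_x / (1 + (1-a_x) m_x) with a_x = 0.5 at
    ages 1+ and a_0 from the infant rule (``"andreev-kingkade"`` piecewise
    in m_0, or ``"classic"`` for 0.07 + 1.7 m_0); the open age gets q = 1
    and e = 1/m.  Columns: age, mx, ax, qx, lx, dx, Lx, Tx, ex.
    """
    sub = records.for_year(year)
    deaths = sub["deaths"].to_numpy(dtype=float)
    exposure = sub["exposure"].to_numpy(dtype=float)
    if np.any(np.isnan(deaths)) or np.any(np.isnan(exposure)):
        raise ValueError(f"year {year}: missing deaths or exposure values")
    bad = (exposure <= 0) & (deaths > 0)
    if np.any(bad):
        raise ValueError(
            f"year {year}: zero exposure with nonzero deaths at ages {np.flatnonzero(bad).tolist()}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = np.where(exposure > 0, deaths / exposure, 0.0)

    n = OPEN_AGE + 1
    ax = np.full(n, 0.5)
    if a0_rule == "andreev-kingkade":
        ax[0] = _a0_andreev_kingkade(mx[0], records.sex)
    elif a0_rule == "classic":
        ax[0] = 0.07 + 1.7 * mx[0]
    else:
        raise ValueError(f"unknown a0 rule {a0_rule!r}")

    qx = mx / (1.0 + (1.0 - ax) * mx)
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    lx = np.empty(n)
    lx[0] = radix
    for x in range(n - 1):
        lx[x + 1] = lx[x] * (1.0 - qx[x])
    dx = lx * qx
    Lx = np.empty(n)
    Lx[:-1] = lx[1:] + ax[:-1] * dx[:-1]
    if mx[-1] > 0:
        ax[-1] = 1.0 / mx[-1]
        Lx[-1] = lx[-1] / mx[-1]
    else:  # nobody reaches the open age
        ax[-1] = 0.0
        Lx[-1] = 0.0
    Tx = Lx[::-1].cumsum()[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)
    return pd.DataFrame(
        {"age": np.arange(n), "mx": mx, "ax": ax, "qx": qx, "lx": lx, "dx": dx,
         "Lx": Lx, "Tx": Tx, "ex": ex}
    )


def deaths_distribution(lt: pd.DataFrame) -> DeathCounts:
    """Normalized life-table death distribution d_x / radix on the integer
    grid; sums to 1 and is invariant to the radix.  The returned
    :class:`DeathCounts` carries fractional weights, which the multinomial
    log-likelihood handles unchanged (only the curvature, not the location,
    of the likelihood depends on the total)."""
    dx = lt["dx"].to_numpy(dtype=float)
    return DeathCounts(grid=AgeGrid(omega=len(dx) - 1), counts=dx / dx.sum())


def simulate_death_counts(
    theta: DirectParams, n: int, grid: AgeGrid | None = None, seed: int | None = None
) -> DeathCounts:
    """One multinomial draw of ``n`` deaths from the mixture's binned
    probabilities, renormalized over the in-range mass so the draw is a
    proper multinomial.  Raises when more than 1% of the mixture mass falls
    outside the grid (an unsuitable theta for count simulation)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = grid or AgeGrid()
    p = bin_probabilities(theta, grid)
    mass = p.sum()
    if mass < 0.99:
        raise ValueError(f"only {mass:.4f} of the mixture mass is in range; theta unsuitable")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(n), p / mass)
    return DeathCounts(grid=grid, counts=counts)
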