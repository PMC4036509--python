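"""Root-architecture and nitrogen-acquisition efficiency variables.

From destructive per-plant measurements at successive sampling days this module
derives, per plant:

    LRL   mean lateral root length = (TRL - PRL) / LRN        [cm]
    TDW   total dry weight         = SDW + RDW                [g]
    TotN  whole-plant N mass       = SDW*%ShootN + RDW*%RootN [g N]
    RDW/TDW  root mass fraction                               [-]

and, per genotype x nitrate group and consecutive sampling interval, the two
integrative efficiency variables:

    NUR  N-uptake rate: N acquired per unit root surface area per day,
         NUR = dTotN / integral(root area dt)                 [g N cm^-2 d^-1]
    NLA  leaf area produced per unit N acquired,
         NLA = dLeafA / dTotN                                 [cm^2 (g N)^-1]

Group means per day are used (plants are destructively sampled, so there is no
within-plant time series) and the root-area integral is the trapezoid between
the two sampling days. Fisher's LSD range test with a letter display compares
the four genotype x nitrate groups at each day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError

PHENOTYPE_COLUMNS = (
    "genotype",
    "nitrate",
    "day",
    "plant_id",
    "prl",
    "lrn",
    "trl",
    "root_area",
    "leaf_area",
    "sdw",
    "rdw",
    "pct_shoot_n",
    "pct_root_n",
)


@dataclass
class PlantRecord:
    """One destructively sampled plant at one sampling day.

    Lengths in cm, areas in cm^2, masses in g, N concentrations in % of dry
    mass. ``lrn`` counts first-to-third-order lateral roots.
    """

    genotype: str
    nitrate: str
    day: float
    plant_id: str
    prl: float
    lrn: float
    trl: float
    root_area: float
    leaf_area: float
    sdw: float
    rdw: float
    pct_shoot_n: float
    pct_root_n: float


@dataclass
class DerivedPlantVariables:
    tdw: float        # g
    totn: float       # g N
    lrl: float        # cm
    rdw_ratio: float  # RDW / TDW


@dataclass
class EfficiencyMetrics:
    """Interval NUR/NLA per group plus the RDW/TDW trajectory.

    ``intervals`` columns: genotype, nitrate, t1, t2, d_totn, area_integral,
    nur, d_leaf_area, nla (NaN where undefined).
    ``rdw_ratio`` columns: genotype, nitrate, day, rdw_ratio.
    """

    intervals: pd.DataFrame
    rdw_ratio: pd.DataFrame
    basis: str = "area"


@dataclass
class LSDGrouping:
    """Fisher-LSD letter display over group means (sorted descending)."""

    means: dict[str, float]
    n_per_group: dict[str, int]
    mse: float
    df_error: int
    alpha: float
    lsd: dict[tuple[str, str], float] = field(repr=False, default_factory=dict)
    letters: dict[str, str] = field(default_factory=dict)


def derive_plant_variables(rec: PlantRecord) -> DerivedPlantVariables:
    """Per-plant derived variables.

    LRL with no lateral roots (LRN = 0) is 0 by convention when TRL equals
    PRL; LRN = 0 with TRL > PRL is an inconsistent record and raises.
    """
    if rec.lrn < 0:
        raise AnalysisError(f"negative lateral root number for plant {rec.plant_id!r}")
    if rec.lrn == 0:
        if rec.trl > rec.prl:
            raise AnalysisError(
                f"plant {rec.plant_id!r}: TRL > PRL with zero lateral roots; LRL undefined"
            )
        lrl = 0.0
    else:
        lrl = (rec.trl - rec.prl) / rec.lrn
    tdw = rec.sdw + rec.rdw
    if tdw <= 0:
        raise AnalysisError(f"plant {rec.plant_id!r}: total dry weight is zero; RDW/TDW undefined")
    totn = rec.sdw * rec.pct_shoot_n / 100.0 + rec.rdw * rec.pct_root_n / 100.0
    return DerivedPlantVariables(tdw=tdw, totn=totn, lrl=lrl, rdw_ratio=rec.rdw / tdw)


def records_to_frame(records: list[PlantRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=list(PHENOTYPE_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[PlantRecord]:
    missing = set(PHENOTYPE_COLUMNS) - set(frame.columns)
    if missing:
        raise AnalysisError(f"phenotype table lacks columns: {sorted(missing)}")
    return [PlantRecord(**{c: row[c] for c in PHENOTYPE_COLUMNS}) for _, row in frame.iterrows()]


def read_phenotypes(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(PHENOTYPE_COLUMNS) - set(frame.columns)
    if missing:
        raise AnalysisError(f"{path}: phenotype table lacks columns {sorted(missing)}")
    return frame


def write_phenotypes(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def derived_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Derived variables for every row of a tidy phenotype table."""
    out = frame.copy()
    derived = [derive_plant_variables(r) for r in frame_to_records(frame)]
    out["tdw"] = [d.tdw for d in derived]
    out["totn"] = [d.totn for d in derived]
    out["lrl"] = [d.lrl for d in derived]
    out["rdw_ratio"] = [d.rdw_ratio for d in derived]
    return out


def interval_efficiencies(
    frame_or_records, basis: str = "area", n_grid: int = 0
) -> EfficiencyMetrics:
    """NUR and NLA per genotype x nitrate group and consecutive day interval.

    Group means of TotN, root area (or RDW with ``basis="rdw"``) and leaf area
    are formed per sampling day; between consecutive days the denominator is
    the trapezoidal integral of the (linearly interpolated) mean area. Setting
    ``n_grid`` refines the internal integration grid, which leaves the result
    unchanged for a linear-in-time area — exposed to make that invariance
    testable. NLA is NaN where dTotN = 0; NUR is NaN where the integrated
    area is 0.
    """
    if basis not in ("area", "rdw"):
        raise ConfigurationError(f"NUR basis must be 'area' or 'rdw', got {basis!r}")
    frame = frame_or_records
    if not isinstance(frame, pd.DataFrame):
        frame = records_to_frame(frame)
    dv = derived_frame(frame)
    denom_col = "root_area" if basis == "area" else "rdw"

    day_means = (
        dv.groupby(["genotype", "nitrate", "day"], observed=False)[
            ["totn", denom_col, "leaf_area", "rdw_ratio"]
        ]
        .mean()
        .reset_index()
        .sort_values(["genotype", "nitrate", "day"])
    )
    rows = []
    for (g, n), grp in day_means.groupby(["genotype", "nitrate"], observed=False):
        if len(grp) < 2:
            raise AnalysisError(f"group ({g}, {n}) has fewer than 2 sampling days")
        days = grp["day"].to_numpy(dtype=float)
        totn = grp["totn"].to_numpy()
        area = grp[denom_col].to_numpy()
        leaf = grp["leaf_area"].to_numpy()
        for k in range(len(days) - 1):
            t1, t2 = days[k], days[k + 1]
            if n_grid > 1:
                tt = np.linspace(t1, t2, n_grid)
                aa = np.interp(tt, [t1, t2], [area[k], area[k + 1]])
                integral = float(np.trapezoid(aa, tt))
            else:
                integral = (t2 - t1) * (area[k] + area[k + 1]) / 2.0
            d_totn = totn[k + 1] - totn[k]
            d_leaf = leaf[k + 1] - leaf[k]
            nur = d_totn / integral if integral > 0 else math.nan
            nla = d_leaf / d_totn if d_totn != 0 else math.nan
            rows.append(
                {
                    "genotype": g,
                    "nitrate": n,
                    "t1": t1,
                    "t2": t2,
                    "d_totn": d_totn,
                    "area_integral": integral,
                    "nur": nur,
                    "d_leaf_area": d_leaf,
                    "nla": nla,
                }
            )
    ratio = day_means[["genotype", "nitrate", "day", "rdw_ratio"]].reset_index(drop=True)
    return EfficiencyMetrics(intervals=pd.DataFrame(rows), rdw_ratio=ratio, basis=basis)


def _letter_labels(k: int) -> list[str]:
    letters = "abcdefghijklmnopqrstuvwxyz"
    return [letters[i % 26] * (i // 26 + 1) for i in range(k)]


def lsd_compare(groups: dict[str, np.ndarray], alpha: float = 0.05) -> LSDGrouping:
    """Fisher's least-significant-difference test with a letter display.

    One-way ANOVA pools the within-group mean square error; for groups i, j
    LSD_ij = t(1 - alpha/2, df_E) * sqrt(MSE * (1/n_i + 1/n_j)) and means
    closer than their LSD share a letter. Letters come from the
    insert-and-absorb algorithm on means sorted descending. A zero MSE
    (identical values within every group) is floored at machine epsilon times
    the squared grand mean so the display stays well-defined.
    """
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if len(groups) < 2:
        raise AnalysisError("LSD comparison needs at least 2 groups")
    values = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, v in values.items():
        if v.size < 2:
            raise AnalysisError(f"group {name!r} has fewer than 2 observations")
    n = {k: int(v.size) for k, v in values.items()}
    means = {k: float(v.mean()) for k, v in values.items()}
    df_error = sum(n.values()) - len(values)
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in values.values())
    mse = sse / df_error
    grand = np.concatenate(list(values.values())).mean()
    floor = np.finfo(float).eps * max(grand ** 2, 1.0)
    mse = max(mse, floor)
    tcrit = stats.t.ppf(1 - alpha / 2, df_error)
    names = sorted(means, key=means.get, reverse=True)
    lsd = {}
    for a in names:
        for b in names:
            if a < b:
                val = tcrit * math.sqrt(mse * (1 / n[a] + 1 / n[b]))
                lsd[(a, b)] = lsd[(b, a)] = val

    # insert-and-absorb on descending means: for each group take the maximal
    # run of groups not significantly different from it, drop runs contained
    # in another, then letter the remaining runs in order
    k = len(names)
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            abs(means[names[i2]] - means[names[j + 1]]) < lsd[(names[i2], names[j + 1])]
            for i2 in range(i, j + 1)
        ):
            j += 1
        runs.append((i, j))
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    maximal = sorted(set(maximal))
    letters = {name: "" for name in names}
    for label, (i, j) in zip(_letter_labels(len(maximal)), maximal):
        for idx in range(i, j + 1):
            letters[names[idx]] += label
    return LSDGrouping(
        means=means, n_per_group=n, mse=mse, df_error=df_error, alpha=alpha,
        lsd=lsd, letters=letters,
    )


def lsd_by_day(
    frame: pd.DataFrame, variable: str, alpha: float = 0.05
) -> pd.DataFrame:
    """LSD letter table for one variable at every sampling day.

    Groups are the genotype x nitrate combinations; the experimental unit is
    whatever one row of ``frame`` represents (per-plant or per-replicate mean).
    """
    rows = []
    for day, sub in frame.groupby("day"):
        groups = {
            f"{g}_{n}": grp[variable].to_numpy()
            for (g, n), grp in sub.groupby(["genotype", "nitrate"], observed=False)
        }
        res = lsd_compare(groups, alpha=alpha)
        for name in res.means:
            rows.append(
                {
                    "day": day,
                    "group": name,
                    "mean": res.means[name],
                    "n": res.n_per_group[name],
                    "letters": res.letters[name],
                }
            )
    return pd.DataFrame(rows)
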