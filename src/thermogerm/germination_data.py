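"""Data model and summary statistics for diurnal-regime germination assays.

A germination assay exposes seed lots to 36 diurnal temperature regimes: a
cool period of 16 h at ``t_cool`` followed by a warm period of 8 h at
``t_warm``, with both temperatures on the 5–40 °C grid in 5 °C steps and
``t_warm >= t_cool`` (constant regimes lie on the diagonal of the half
grid).  Each regime is scored as the cumulative germination percentage of
three replicates of 50 seeds at the assay endpoint (15–20 days).

Percentages are stored as printed (one decimal); model fitting is always
done on fractions in [0, 1] — see :func:`to_pairs`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Callable, Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TemperatureRegime",
    "GerminationObservation",
    "GerminationTable",
    "ProfileSummary",
    "CULTIVARS",
    "GRID_TEMPS",
    "half_grid_regimes",
    "load_table",
    "write_table",
    "builtin_table",
    "reconstruct_replicates",
    "to_pairs",
    "summarize_profile",
    "summary_frame",
]

#: Temperatures tested in the reference assay (°C).
GRID_TEMPS: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40)

#: Cultivars with packaged reference tables.
CULTIVARS: tuple[str, ...] = (
    "Midnight II",
    "Diva",
    "Rugby II",
    "Leopard",
    "Sapphire",
)

_CANONICAL_COLUMNS = [
    "cultivar",
    "t_cool_c",
    "t_warm_c",
    "mean_pct",
    "sd_pct",
    "n_reps",
    "n_seeds",
]


class TemperatureRegime(NamedTuple):
    """A diurnal regime: 16 h at ``t_cool`` then 8 h at ``t_warm`` (°C)."""

    t_cool: float
    t_warm: float

    def validate(self) -> "TemperatureRegime":
        if self.t_warm < self.t_cool:
            raise ValueError(
                f"regime ({self.t_cool}, {self.t_warm}): warm-period "
                "temperature must be >= cool-period temperature"
            )
        return self

    @property
    def delta(self) -> float:
        """Diurnal differential t_warm − t_cool (°C)."""
        return self.t_warm - self.t_cool


def half_grid_regimes(temps: Sequence[float] = GRID_TEMPS) -> list[TemperatureRegime]:
    """All regimes (t_cool, t_warm) with t_warm >= t_cool on the grid."""
    return [
        TemperatureRegime(tc, tw) for tc in temps for tw in temps if tw >= tc
    ]


@dataclass(frozen=True)
class GerminationObservation:
    """One regime's germination outcome: mean ± SD over replicates (%)."""

    regime: TemperatureRegime
    mean_pct: float
    sd_pct: float
    n_reps: int = 3
    n_seeds: int = 50
    replicate_pcts: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.regime.validate()
        if not 0.0 <= self.mean_pct <= 100.0:
            raise ValueError(
                f"regime {tuple(self.regime)}: mean_pct {self.mean_pct} "
                "outside [0, 100]"
            )
        if self.sd_pct < 0.0:
            raise ValueError(f"regime {tuple(self.regime)}: negative sd_pct")
        if self.replicate_pcts is not None:
            if len(self.replicate_pcts) != self.n_reps:
                raise ValueError(
                    f"regime {tuple(self.regime)}: expected {self.n_reps} "
                    f"replicates, got {len(self.replicate_pcts)}"
                )


@dataclass
class GerminationTable:
    """One cultivar's full 36-regime assay."""

    cultivar: str
    observations: list[GerminationObservation]
    temps: tuple[float, ...] = GRID_TEMPS

    def __post_init__(self) -> None:
        expected = set(map(tuple, half_grid_regimes(self.temps)))
        seen: set[tuple[float, float]] = set()
        for obs in self.observations:
            key = tuple(obs.regime)
            if key in seen:
                raise ValueError(
                    f"{self.cultivar}: duplicate regime {key}"
                )
            seen.add(key)
        missing = expected - seen
        extra = seen - expected
        if missing:
            raise ValueError(
                f"{self.cultivar}: missing regime cell(s) "
                f"{sorted(missing)}"
            )
        if extra:
            raise ValueError(
                f"{self.cultivar}: unexpected regime cell(s) {sorted(extra)}"
            )
        self._by_regime = {tuple(o.regime): o for o in self.observations}

    def __len__(self) -> int:
        return len(self.observations)

    def cell(self, t_cool: float, t_warm: float) -> GerminationObservation:
        try:
            return self._by_regime[(t_cool, t_warm)]
        except KeyError:
            raise KeyError(
                f"{self.cultivar}: no regime ({t_cool}, {t_warm})"
            ) from None

    def means(self) -> np.ndarray:
        """Regime means (%) in canonical (t_cool, t_warm) sort order."""
        return np.array(
            [o.mean_pct for o in sorted(self.observations, key=lambda o: tuple(o.regime))]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cultivar": self.cultivar,
                "t_cool_c": o.regime.t_cool,
                "t_warm_c": o.regime.t_warm,
                "mean_pct": o.mean_pct,
                "sd_pct": o.sd_pct,
                "n_reps": o.n_reps,
                "n_seeds": o.n_seeds,
            }
            for o in sorted(self.observations, key=lambda o: tuple(o.regime))
        ]
        return pd.DataFrame(rows, columns=_CANONICAL_COLUMNS)


@dataclass(frozen=True)
class ProfileSummary:
    """Whole-profile summary metrics (all in %, or NaN when undefined)."""

    cultivar: str
    profile_mean: float
    pct_regimes_some: float
    max_germination: float
    mean_of_some: float
    mean_of_optima: float
    optimum_regimes: tuple[TemperatureRegime, ...]


def load_table(source, cultivar: str) -> GerminationTable:
    """Read one cultivar's table from a canonical germination CSV.

    The canonical format has header
    ``cultivar,t_cool_c,t_warm_c,mean_pct,sd_pct,n_reps,n_seeds`` and one
    row per regime.  Rows with ``t_warm_c < t_cool_c`` or means outside
    [0, 100] are rejected, as are duplicate or missing regimes.
    """
    df = pd.read_csv(source)
    missing_cols = set(_CANONICAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing column(s): {sorted(missing_cols)}")
    df = df[df["cultivar"] == cultivar]
    if df.empty:
        raise ValueError(f"no rows for cultivar {cultivar!r}")
    obs = [
        GerminationObservation(
            regime=TemperatureRegime(float(r.t_cool_c), float(r.t_warm_c)),
            mean_pct=float(r.mean_pct),
            sd_pct=float(r.sd_pct),
            n_reps=int(r.n_reps),
            n_seeds=int(r.n_seeds),
        )
        for r in df.itertuples()
    ]
    return GerminationTable(cultivar=cultivar, observations=obs)


def write_table(table: GerminationTable, path) -> None:
    """Write a table in the canonical CSV format (deterministic bytes)."""
    lines = [",".join(_CANONICAL_COLUMNS)]
    for o in sorted(table.observations, key=lambda o: tuple(o.regime)):
        lines.append(
            f"{table.cultivar},{o.regime.t_cool:g},{o.regime.t_warm:g},"
            f"{o.mean_pct:.1f},{o.sd_pct:.1f},{o.n_reps},{o.n_seeds}"
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)


def builtin_table(cultivar: str) -> GerminationTable:
    """Return the packaged reference assay for one of the five cultivars.

    Note on provenance: the packaged tables are transcribed from a
    published Kentucky-bluegrass assay whose per-cultivar table captions
    disagree with its own summary statistics and narrative for three
    cultivars; labels here follow the summary/narrative assignment (see
    the methods note).
    """
    if cultivar not in CULTIVARS:
        raise ValueError(
            f"unknown cultivar {cultivar!r}; available: {', '.join(CULTIVARS)}"
        )
    data = resources.files("thermogerm.data").joinpath("germination_tables.csv")
    with data.open("r", encoding="utf-8") as fh:
        return load_table(fh, cultivar)


def reconstruct_replicates(obs: GerminationObservation) -> GerminationObservation:
    """Reconstruct a plausible replicate triple {m−s, m, m+s} for a cell.

    The sample SD (ddof=1) of {m−s, m, m+s} is exactly s, so the raw
    triple preserves both printed moments.  Values are then clamped to
    [0, 100] and rounded to the nearest multiple of 100/n_seeds (one seed),
    which can shift the realized mean slightly for cells near the bounds;
    the realized triple is what downstream replicate-level fitting sees.

    This is an explicit approximation used only when replicate-level
    fitting is requested; mean-level fitting needs no reconstruction.
    """
    if obs.n_reps != 3:
        raise ValueError("replicate reconstruction assumes 3 replicates")
    m, s = obs.mean_pct, obs.sd_pct
    raw = np.array([m - s, m, m + s])
    step = 100.0 / obs.n_seeds
    clamped = np.clip(raw, 0.0, 100.0)
    # round half away from zero so e.g. 73.2 -> 74 with a 2 % step
    rounded = np.floor(clamped / step + 0.5) * step
    return replace(obs, replicate_pcts=tuple(float(v) for v in rounded))


def to_pairs(
    table: GerminationTable,
    level: Literal["mean", "replicate"] = "mean",
) -> list[tuple[float, float, float]]:
    """Flatten a table to (t_cool, t_warm, germination fraction) triples.

    ``mean`` yields one pair per regime (36); ``replicate`` yields one per
    replicate (108), reconstructing replicates on demand where absent.
    """
    pairs: list[tuple[float, float, float]] = []
    for obs in sorted(table.observations, key=lambda o: tuple(o.regime)):
        t1, t2 = obs.regime
        if level == "mean":
            pairs.append((t1, t2, obs.mean_pct / 100.0))
        elif level == "replicate":
            if obs.replicate_pcts is None:
                obs = reconstruct_replicates(obs)
            for pct in obs.replicate_pcts:
                pairs.append((t1, t2, pct / 100.0))
        else:
            raise ValueError(f"unknown level {level!r}")
    return pairs


# --------------------------------------------------------------------------
# Optimum-regime rules
#
# "Optimum germination" is conventionally the set of regimes whose mean is
# not lower than the maximum germination minus one half of its 95 %
# confidence interval.  The source assay leaves the CI computation
# unstated (SD vs SE, t vs z), so the half-width h is a pluggable rule.

def t_ci_halfwidth(table: GerminationTable) -> float:
    """Default rule: h = t(0.975, n−1) · sd_max / √n for the maximum cell."""
    best = max(table.observations, key=lambda o: o.mean_pct)
    tcrit = stats.t.ppf(0.975, best.n_reps - 1)
    return float(tcrit * best.sd_pct / math.sqrt(best.n_reps))


def z_sd_halfwidth(table: GerminationTable) -> float:
    """Alternative: h = 1.96 · sd_max with the printed spread taken as-is."""
    best = max(table.observations, key=lambda o: o.mean_pct)
    return float(1.96 * best.sd_pct)


def top_k_rule(k: int) -> Callable[[GerminationTable], float]:
    """Fixed-count rule: h chosen so exactly the top-k cells are optimal."""

    def rule(table: GerminationTable) -> float:
        means = np.sort([o.mean_pct for o in table.observations])[::-1]
        k_eff = min(k, len(means))
        return float(means[0] - means[k_eff - 1])

    return rule


OPTIMUM_RULES: dict[str, Callable[[GerminationTable], float]] = {
    "t_ci": t_ci_halfwidth,
    "z_sd": z_sd_halfwidth,
}


def summarize_profile(
    table: GerminationTable,
    optimum_rule: str | Callable[[GerminationTable], float] = "t_ci",
) -> ProfileSummary:
    """Summary metrics of a temperature–germination profile.

    ``profile_mean`` averages all 36 regime means; ``pct_regimes_some`` is
    the percentage of regimes with any germination; ``mean_of_some``
    averages only germinating regimes; optimum regimes are those within h
    of the maximum, with h given by ``optimum_rule``.  For an all-zero
    profile the conditional means are undefined and reported as NaN.
    """
    rule = OPTIMUM_RULES[optimum_rule] if isinstance(optimum_rule, str) else optimum_rule
    means = np.array([o.mean_pct for o in table.observations])
    n = len(means)
    some = means > 0.0
    profile_mean = float(means.mean())
    pct_some = float(100.0 * some.sum() / n)
    max_germ = float(means.max())
    if not some.any():
        return ProfileSummary(
            cultivar=table.cultivar,
            profile_mean=profile_mean,
            pct_regimes_some=0.0,
            max_germination=max_germ,
            mean_of_some=float("nan"),
            mean_of_optima=float("nan"),
            optimum_regimes=(),
        )
    mean_some = float(means[some].mean())
    h = rule(table)
    optima = tuple(
        o.regime
        for o in sorted(table.observations, key=lambda o: tuple(o.regime))
        if o.mean_pct >= max_germ - h
    )
    optima_means = [table.cell(*r).mean_pct for r in optima]
    return ProfileSummary(
        cultivar=table.cultivar,
        profile_mean=profile_mean,
        pct_regimes_some=pct_some,
        max_germination=max_germ,
        mean_of_some=mean_some,
        mean_of_optima=float(np.mean(optima_means)),
        optimum_regimes=optima,
    )


def summary_frame(
    tables: Iterable[GerminationTable],
    optimum_rule: str | Callable[[GerminationTable], float] = "t_ci",
) -> pd.DataFrame:
    """Metric × cultivar summary table for several assays."""
    summaries = [summarize_profile(t, optimum_rule) for t in tables]
    metrics = [
        ("Profile mean", "profile_mean"),
        ("Regimes with some germination", "pct_regimes_some"),
        ("Maximum germination", "max_germination"),
        ("Mean of some germination", "mean_of_some"),
        ("Mean of optima", "mean_of_optima"),
    ]
    data = {
        s.cultivar: [round(getattr(s, attr), 1) for _, attr in metrics]
        for s in summaries
    }
    return pd.DataFrame(data, index=[name for name, _ in metrics])
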