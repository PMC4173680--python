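"""Species-level trait aggregation and division-of-labour measures.

Literature and specimen data arrive as observation-level records (one mean
per population study, with an optional sample size).  Per-species values are
sample-size-weighted means; the two division-of-labour measures are

* worker size variation (WSV): the coefficient of variation of worker head
  width, ``100 * sigma / xbar``, with ``sigma`` the sample standard
  deviation of the observation means and ``xbar`` the weighted species
  mean — a proxy for non-reproductive division of labour;
* queen-worker dimorphism (QWD): the percentage difference between mean
  queen and mean worker head width, ``100 * (Q - W) / Q`` by default — a
  proxy for reproductive division of labour.

Observation sample sizes missing from the source are taken as 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ("worker_head_width", "queen_head_width", "colony_size", "mating_system")

OBSERVATION_COLUMNS = [
    "species", "trait", "mean", "sd", "n", "source",
    "lat", "lon", "locality_precision_km2",
]

__all__ = [
    "ObservationRecord",
    "weighted_species_mean",
    "worker_size_variation",
    "queen_worker_dimorphism",
    "transform_trait",
    "sampling_bias_check",
    "compare_measurement_sources",
    "aggregate_observations",
    "transform_table",
    "read_observations",
    "write_species_table",
]


@dataclass
class ObservationRecord:
    """One literature/specimen observation of one trait for one species."""

    species: str
    trait: str
    mean: float
    sd: float | None = None
    n: int | None = None
    source: str = ""
    lat: float | None = None
    lon: float | None = None
    locality_precision_km2: float | None = None

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.mean < 0:
            raise ValueError(f"negative mean for {self.species}/{self.trait}")
        if self.trait == "colony_size" and self.mean < 1:
            raise ValueError(f"colony size < 1 worker for {self.species}")
        if self.n is not None and self.n < 1:
            raise ValueError(f"sample size < 1 for {self.species}/{self.trait}")


def _n_or_one(rec) -> float:
    n = rec.n if hasattr(rec, "n") else rec
    return 1.0 if n is None or (isinstance(n, float) and math.isnan(n)) else float(n)


def weighted_species_mean(observations) -> tuple[float, int]:
    """Sample-size-weighted mean of observation means.

    Returns ``(mean, total_n)`` where ``mean = sum(x_s * n_s) / sum(n_s)``
    and ``total_n = sum(n_s)``; observations without a sample size count as
    ``n_s = 1``.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations")
    ns = np.array([_n_or_one(o) for o in obs])
    xs = np.array([o.mean for o in obs], dtype=float)
    total = ns.sum()
    return float((xs * ns).sum() / total), int(total)


def worker_size_variation(observations) -> float | None:
    """Coefficient of variation (percent) of worker head width.

    ``100 * sigma / xbar`` with ``sigma`` the unweighted sample (n-1)
    standard deviation of the observation means and ``xbar`` the weighted
    species mean.  Returns ``None`` (undefined) with fewer than two
    observations; a zero mean raises.
    """
    obs = list(observations)
    if len(obs) < 2:
        return None
    xbar, _ = weighted_species_mean(obs)
    if xbar == 0:
        raise ValueError("zero mean head width: CV undefined")
    sigma = float(np.std([o.mean for o in obs], ddof=1))
    return 100.0 * sigma / xbar


def queen_worker_dimorphism(mean_queen_hw: float, mean_worker_hw: float,
                            denominator: str = "queen") -> float:
    """Percentage difference between queen and worker mean head width.

    Default convention ``100 * (Q - W) / Q`` (bounded above by 100 when
    Q >= W); ``denominator="worker"`` gives ``100 * (Q - W) / W``.  Negative
    values mean workers are larger than queens.
    """
    if mean_queen_hw <= 0 or mean_worker_hw <= 0:
        raise ValueError("head widths must be positive")
    if denominator == "queen":
        return 100.0 * (mean_queen_hw - mean_worker_hw) / mean_queen_hw
    if denominator == "worker":
        return 100.0 * (mean_queen_hw - mean_worker_hw) / mean_worker_hw
    raise ValueError("denominator must be 'queen' or 'worker'")


def transform_trait(value: float, kind: str, species: str = "?",
                    trait: str = "?") -> float:
    """Normalising transformation: 'sqrt', 'ln' or 'identity'."""
    if kind == "identity":
        return float(value)
    if kind == "sqrt":
        if value < 0:
            raise ValueError(f"sqrt of negative value for {species}/{trait}")
        return math.sqrt(value)
    if kind == "ln":
        if value <= 0:
            raise ValueError(f"ln of non-positive value for {species}/{trait}")
        return math.log(value)
    raise ValueError(f"unknown transformation {kind!r}")


def sampling_bias_check(species_values) -> tuple[float, float]:
    """OLS of a transformed trait on ln(total sample size) across species.

    A non-significant slope indicates the trait measure is not driven by
    study effort.  Returns ``(slope, two-sided p)``.
    """
    pairs = list(species_values)
    if len(pairs) < 3:
        raise ValueError("need at least 3 species")
    y = np.array([p[0] for p in pairs], dtype=float)
    x = np.array([p[1] for p in pairs], dtype=float)
    res = stats.linregress(x, y)
    p = 0.0 if np.isnan(res.pvalue) and abs(res.slope) > 0 else res.pvalue
    if np.isnan(p):  # constant response: slope 0, no evidence
        return float(res.slope), 1.0
    return float(res.slope), float(p)


def compare_measurement_sources(paired_values) -> tuple[float, int, float]:
    """Paired t-test between two measurement sources for the same species.

    Returns ``(t, df, p)`` with ``df = n - 1``.  All-zero differences give
    ``t = 0, p = 1`` by convention.
    """
    pairs = list(paired_values)
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    d = a - b
    df = len(d) - 1
    if np.allclose(d, 0.0):
        return 0.0, df, 1.0
    res = stats.ttest_rel(a, b)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero-variance nonzero differences: infinite evidence
        return math.copysign(math.inf, d.mean()), df, 0.0
    return t, df, p


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _records_from_frame(df: pd.DataFrame) -> list[ObservationRecord]:
    def opt(row, name, cast=float):
        v = row.get(name, np.nan)
        return None if pd.isna(v) else cast(v)

    recs = []
    for _, row in df.iterrows():
        recs.append(ObservationRecord(
            species=row["species"], trait=row["trait"], mean=float(row["mean"]),
            sd=opt(row, "sd"), n=opt(row, "n", int),
            source="" if pd.isna(row.get("source", np.nan)) else str(row.get("source")),
            lat=opt(row, "lat"), lon=opt(row, "lon"),
            locality_precision_km2=opt(row, "locality_precision_km2"),
        ))
    return recs


def aggregate_observations(observations, qwd_denominator: str = "queen",
                           default_mating_system: int = 0):
    """Aggregate observation records into a per-species trait table.

    Accepts a list of :class:`ObservationRecord` or a DataFrame with the
    observation columns.  Returns ``(table, provenance)``: the table holds
    one row per species (weighted means, WSV, QWD, mating system); the
    provenance frame lists the contributing ``total_n`` per species x trait.
    WSV is left missing for species with fewer than two head-width
    observations; QWD requires both head widths.  Mating system defaults to
    monandrous (0) when unrecorded.
    """
    if isinstance(observations, pd.DataFrame):
        observations = _records_from_frame(observations)
    by_species: dict[str, dict[str, list[ObservationRecord]]] = {}
    for rec in observations:
        by_species.setdefault(rec.species, {}).setdefault(rec.trait, []).append(rec)

    rows, prov = [], []
    for sp in sorted(by_species):
        groups = by_species[sp]
        row: dict = {"species": sp}
        for trait in ("colony_size", "worker_head_width", "queen_head_width"):
            if trait in groups:
                mean, total_n = weighted_species_mean(groups[trait])
                row[trait] = mean
                row[trait + "_n"] = total_n
                prov.append({"species": sp, "trait": trait, "total_n": total_n,
                             "n_observations": len(groups[trait])})
        if "worker_head_width" in groups:
            cv = worker_size_variation(groups["worker_head_width"])
            if cv is not None:
                row["worker_size_variation"] = cv
                row["worker_head_width_sd"] = float(
                    np.std([o.mean for o in groups["worker_head_width"]], ddof=1))
        if "worker_head_width" in row and "queen_head_width" in row:
            row["queen_worker_dimorphism"] = queen_worker_dimorphism(
                row["queen_head_width"], row["worker_head_width"],
                denominator=qwd_denominator)
        if "mating_system" in groups:
            row["mating_system"] = int(max(o.mean for o in groups["mating_system"]))
        else:
            row["mating_system"] = default_mating_system
        rows.append(row)
    table = pd.DataFrame(rows).set_index("species")
    return table, pd.DataFrame(prov)


def transform_table(table: pd.DataFrame, transforms: dict[str, str],
                    on_error: str = "raise"):
    """Apply named transformations column-wise.

    ``transforms`` maps column name -> {'sqrt', 'ln', 'identity'}.  Returns
    ``(frame, provenance)`` where the frame holds transformed columns named
    ``<col>_<kind>`` (identity keeps the name) and provenance records the
    transformation applied per cell-domain outcome.  ``on_error="drop"``
    turns domain violations (e.g. ln of a non-positive dimorphism) into
    missing values, so the species is later dropped from models using that
    trait, instead of raising.
    """
    if on_error not in ("raise", "drop"):
        raise ValueError("on_error must be 'raise' or 'drop'")
    out = table.copy()
    prov = []
    for col, kind in transforms.items():
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
        name = col if kind == "identity" else f"{col}_{kind}"
        vals = []
        for sp, v in table[col].items():
            if pd.isna(v):
                vals.append(np.nan)
                continue
            try:
                vals.append(transform_trait(v, kind, species=str(sp), trait=col))
            except ValueError:
                if on_error == "raise":
                    raise
                vals.append(np.nan)
                prov.append({"column": col, "transform": kind, "output": name,
                             "species": str(sp), "note": "domain violation -> missing"})
        out[name] = vals
        prov.append({"column": col, "transform": kind, "output": name,
                     "species": "", "note": ""})
    return out, pd.DataFrame(prov)


def read_observations(path) -> pd.DataFrame:
    """Read the observation CSV (header row, UTF-8)."""
    df = pd.read_csv(path)
    missing = [c for c in ("species", "trait", "mean") if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    for c in OBSERVATION_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return df[OBSERVATION_COLUMNS]


def write_species_table(table: pd.DataFrame, path, provenance: pd.DataFrame | None = None,
                        provenance_path=None) -> None:
    table.to_csv(path)
    if provenance is not None and provenance_path is not None:
        provenance.to_csv(provenance_path, index=False)
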