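"""Synthetic regionalized hub-and-spoke transfer data with known ground truth.

The real national transfer registry is access-restricted, so every pipeline
stage is exercised against generated data whose structural parameters are
planted and recorded in a :class:`GroundTruthLedger`:

* a hospital registry clustered into referral regions, each with designated
  base (hub) EDs serving the largest populations;
* planned transfer-in partner counts that grow linearly with served
  population (slope ``target_slope`` partners per million residents), which
  concentrates in-degree on hubs and yields a heavy-tailed, scale-free-like
  distribution;
* sender selection favoring same-region hospitals — strongly so when the
  receiver is a hub — producing the regionalized hub-and-spoke pattern;
* dyadic reciprocity planted exactly at ``reciprocity_target`` by converting
  asymmetric dyads to mutual ones (weak reverse arcs) or trimming chance
  mutuals;
* heavy-tailed (discretized log-normal) arc weights spanning the <36 and
  >365 transfers-per-3-years thresholds;
* per-year volumes scaling by ``yearly_growth``; and
* a small additive discharge-probability boost for transfers sent by planted
  "distributor" hospitals (most negative net connectivity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .netbuild import Hospital
from .records import RECORD_COLUMNS, TIME_BANDS

_BAND_START = {"7a-3p": 7, "3p-11p": 15, "11p-7a": 23}


def _default_config_dict() -> dict:
    text = (
        resources.files("transfernet")
        .joinpath("_generator_defaults.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


class GeneratorConfig(BaseModel):
    """Tunable parameters of the synthetic transfer-data generator.

    Defaults are loaded from the packaged calibration file
    ``_generator_defaults.yaml``; any field can be overridden at
    construction or via :meth:`from_yaml`.
    """

    n_regions: int = Field(ge=1)
    hospitals_per_region: tuple[int, int]
    n_base_per_region: int = Field(ge=1)
    population_range: tuple[float, float]
    target_slope: float
    in_degree_noise_sd: float = Field(ge=0)
    hub_attachment_strength: float = Field(ge=0)
    region_affinity: float = Field(ge=0)
    reciprocity_target: float = Field(ge=0, le=1)
    weight_distribution: dict
    reciprocal_weight_mean: float = Field(ge=0)
    years: list[int]
    yearly_growth: float = Field(gt=0)
    age_mean: float
    age_sd: float
    age_max: int
    base_discharge_rate: float = Field(ge=0, le=1)
    distributor_discharge_boost: float
    distributor_quantile: float = Field(gt=0, lt=1)
    record_attribute_tables: dict[str, dict[str, float]]
    seed: int = 0

    def __init__(self, **overrides):
        merged = _default_config_dict()
        merged.update(overrides)
        super().__init__(**merged)

    @field_validator("hospitals_per_region", "population_range", mode="before")
    @classmethod
    def _as_tuple(cls, v):
        lo, hi = v
        if lo > hi:
            raise ValueError("range must be (low, high) with low <= high")
        return (lo, hi)

    @model_validator(mode="after")
    def _check_tables(self):
        for name, table in self.record_attribute_tables.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-3:
                raise ValueError(
                    f"probability table {name!r} sums to {total}, not 1"
                )
        if not self.years:
            raise ValueError("years must be non-empty")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class GroundTruthLedger:
    """Planned quantities of one generated dataset, for recovery checks."""

    arc_pair_counts: dict[tuple[str, str], int]
    per_year_counts: dict[int, int]
    planted_hub_ids: list[str]
    planted_distributor_ids: list[str]
    planned_in_degrees: dict[str, int]
    true_slope: float
    true_reciprocity: float
    true_discharge_rates: tuple[float, float]  # (distributor, other senders)
    extra: dict = dc_field(default_factory=dict)

    @property
    def total_transfers(self) -> int:
        return sum(self.arc_pair_counts.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "arc_pair_counts": {
                f"{s}->{r}": w for (s, r), w in sorted(self.arc_pair_counts.items())
            },
            "per_year_counts": {str(y): c for y, c in sorted(self.per_year_counts.items())},
            "planted_hub_ids": self.planted_hub_ids,
            "planted_distributor_ids": self.planted_distributor_ids,
            "planned_in_degrees": dict(sorted(self.planned_in_degrees.items())),
            "true_slope": self.true_slope,
            "true_reciprocity": self.true_reciprocity,
            "true_discharge_rates": list(self.true_discharge_rates),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# --------------------------------------------------------------------------
# Registry generation
# --------------------------------------------------------------------------

def generate_registry(
    config: GeneratorConfig, seed: int | None = None
) -> list[Hospital]:
    """Generate a regionalized hospital registry.

    Region centroids sit on a jittered grid over an abstract 10x10-degree
    planar box; hospitals are scattered around their region centroid, hubs
    tightly so. Hub (base) hospitals draw served populations from the top
    half of ``population_range``, spokes from the bottom fifth, reflecting
    that designated hubs serve whole regions.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    k = config.n_regions
    side = int(np.ceil(np.sqrt(k)))
    spacing = 10.0 / side
    centroids = []
    for i in range(k):
        gx, gy = i % side, i // side
        centroids.append(
            (
                (gx + 0.5) * spacing + rng.uniform(-0.15, 0.15) * spacing,
                (gy + 0.5) * spacing + rng.uniform(-0.15, 0.15) * spacing,
            )
        )

    lo, hi = config.population_range
    lo_h, hi_h = config.hospitals_per_region
    hospitals: list[Hospital] = []
    for r, (cx, cy) in enumerate(centroids, start=1):
        region_id = f"R{r:02d}"
        n_hosp = int(rng.integers(lo_h, hi_h + 1))
        n_base = min(config.n_base_per_region, n_hosp)
        for j in range(1, n_hosp + 1):
            is_base = j <= n_base
            jitter = 0.05 if is_base else 0.35
            lon = cx + rng.normal(0, jitter)
            lat = cy + rng.normal(0, jitter)
            if lo == hi:
                pop = float(lo)
            elif is_base:
                pop = float(rng.uniform(lo + 0.5 * (hi - lo), hi))
            else:
                pop = float(rng.uniform(lo, lo + 0.25 * (hi - lo)))
            hospitals.append(
                Hospital(
                    hospital_id=f"{region_id}H{j:02d}",
                    name=("Base " if is_base else "") + f"Hospital {region_id}-{j:02d}",
                    region_id=region_id,
                    is_base=is_base,
                    longitude=round(lon, 6),
                    latitude=round(lat, 6),
                    population_served=round(pop),
                )
            )
    return hospitals


# --------------------------------------------------------------------------
# Transfer generation
# --------------------------------------------------------------------------

def _plan_arcs(
    registry: list[Hospital], config: GeneratorConfig, rng: np.random.Generator
) -> tuple[dict[tuple[str, str], bool], dict[str, int], float]:
    """Plan the binary arc structure.

    Returns (arcs: pair -> is_reciprocal_addition, planned in-degrees,
    realized dyadic reciprocity).
    """
    ids = [h.hospital_id for h in registry]
    by_id = {h.hospital_id: h for h in registry}
    n = len(ids)
    pop_m = np.array([by_id[v].population_served / 1e6 for v in ids])

    planned = {}
    for i, v in enumerate(ids):
        d = int(round(rng.normal(config.target_slope * pop_m[i],
                                 config.in_degree_noise_sd)))
        planned[v] = max(0, min(n - 1, d))

    arcs: dict[tuple[str, str], bool] = {}
    region = np.array([by_id[v].region_id for v in ids])
    for i, v in enumerate(ids):
        d = planned[v]
        if d == 0:
            continue
        same = region == region[i]
        w = np.ones(n) + config.region_affinity * same
        if by_id[v].is_base:
            w += config.hub_attachment_strength * same
        w[i] = 0.0
        senders = rng.choice(ids, size=d, replace=False, p=w / w.sum())
        for s in senders:
            arcs[(str(s), v)] = False

    # plant dyadic reciprocity exactly: mutual / (mutual + asymmetric)
    dirs: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for s, r in arcs:
        key = (s, r) if s < r else (r, s)
        dirs.setdefault(key, []).append((s, r))
    mutual = [k for k, v in dirs.items() if len(v) == 2]
    asym = [k for k, v in dirs.items() if len(v) == 1]
    n_dyads = len(dirs)
    if n_dyads == 0:
        if config.reciprocity_target > 0:
            raise ValueError("reciprocity target infeasible: no connected dyads")
        return arcs, planned, 0.0
    m_target = int(round(config.reciprocity_target * n_dyads))
    if len(mutual) < m_target:
        promote = rng.choice(len(asym), size=m_target - len(mutual), replace=False)
        for idx in promote:
            (s, r) = dirs[asym[idx]][0]
            arcs[(r, s)] = True
    elif len(mutual) > m_target:
        demote = rng.choice(len(mutual), size=len(mutual) - m_target, replace=False)
        for idx in demote:
            drop = dirs[mutual[idx]][int(rng.integers(2))]
            del arcs[drop]
    return arcs, planned, m_target / n_dyads


def _sample_level(
    rng: np.random.Generator, table: dict[str, float], size: int
) -> np.ndarray:
    levels = list(table.keys())
    probs = np.array([table[l] for l in levels], dtype=float)
    return rng.choice(levels, size=size, p=probs / probs.sum())


def generate_transfers(
    registry: list[Hospital],
    config: GeneratorConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """Generate patient-level transfer records realizing the planted structure.

    Returns the canonical records frame (the dialect ``read_transfers``
    emits) and the ground-truth ledger. Identical seed and config give a
    byte-identical frame.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arcs, planned, true_recip = _plan_arcs(registry, config, rng)

    wd = config.weight_distribution
    if wd.get("law", "lognormal") != "lognormal":
        raise ValueError(f"unsupported weight law {wd.get('law')!r}")
    pair_counts: dict[tuple[str, str], int] = {}
    for pair in sorted(arcs):
        if arcs[pair]:  # weak reverse arc closing a mutual dyad
            w = 1 + int(rng.poisson(config.reciprocal_weight_mean))
        else:
            w = max(1, int(round(rng.lognormal(wd["mu"], wd["sigma"]))))
        pair_counts[pair] = w

    years = sorted(config.years)
    growth = np.array([config.yearly_growth ** i for i in range(len(years))])
    year_probs = growth / growth.sum()

    # planted distributors: bottom quantile of net connectivity among senders
    in_deg: dict[str, int] = {}
    out_deg: dict[str, int] = {}
    for s, r in pair_counts:
        out_deg[s] = out_deg.get(s, 0) + 1
        in_deg[r] = in_deg.get(r, 0) + 1
    senders = sorted(out_deg)
    netc = np.array([in_deg.get(s, 0) - out_deg[s] for s in senders], dtype=float)
    distributors: list[str] = []
    if senders:
        cutoff = np.quantile(netc, config.distributor_quantile)
        distributors = [s for s, v in zip(senders, netc) if v <= cutoff]
    dist_set = set(distributors)

    # expand arcs into per-year record slots
    sender_col, receiver_col, year_col = [], [], []
    per_year = {y: 0 for y in years}
    for pair in sorted(pair_counts):
        counts = rng.multinomial(pair_counts[pair], year_probs)
        for y, c in zip(years, counts):
            per_year[y] += int(c)
            sender_col.extend([pair[0]] * int(c))
            receiver_col.extend([pair[1]] * int(c))
            year_col.extend([y] * int(c))

    n = len(sender_col)
    sender = np.array(sender_col)
    receiver = np.array(receiver_col)
    year = np.array(year_col, dtype=int)

    # departure timestamps: uniform date in year, hour from the time-band table
    year_start = pd.to_datetime({"year": year, "month": 1, "day": 1})
    days_in_year = np.where(pd.DatetimeIndex(year_start).is_leap_year, 366, 365)
    day = (rng.random(n) * days_in_year).astype(int)
    band = _sample_level(rng, config.record_attribute_tables["time_band"], n)
    hour = np.array([
        (_BAND_START[b] + int(o)) % 24
        for b, o in zip(band, rng.integers(0, 8, size=n))
    ])
    depart = (
        year_start
        + pd.to_timedelta(day, unit="D")
        + pd.to_timedelta(hour, unit="h")
        + pd.to_timedelta(rng.integers(0, 60, size=n), unit="m")
        + pd.to_timedelta(rng.integers(0, 60, size=n), unit="s")
    )
    depart = pd.Series(depart).dt.floor("s")
    arrive = depart + pd.to_timedelta(rng.integers(30, 361, size=n), unit="m")

    age = np.clip(
        np.round(rng.normal(config.age_mean, config.age_sd, size=n)),
        0, config.age_max,
    ).astype(int)
    sex = _sample_level(rng, config.record_attribute_tables["sex"], n)
    reason = _sample_level(rng, config.record_attribute_tables["reason"], n)
    reason = pd.Series(reason).replace({"missing": pd.NA})
    condition = _sample_level(rng, config.record_attribute_tables["condition"], n)
    surgery = _sample_level(rng, config.record_attribute_tables["surgery"], n)

    # disposition: discharge probability depends on the sender's planted role
    disp_table = dict(config.record_attribute_tables["disposition"])
    p_disch_other = {
        k: v for k, v in disp_table.items() if k != "discharged_outpatient"
    }
    other_levels = list(p_disch_other.keys())
    other_probs = np.array([p_disch_other[k] for k in other_levels])
    other_probs = other_probs / other_probs.sum()
    p_a = config.base_discharge_rate + config.distributor_discharge_boost
    p_b = config.base_discharge_rate
    p_disch = np.where(np.isin(sender, list(dist_set)), p_a, p_b)
    discharged = rng.random(n) < p_disch
    other_draw = rng.choice(other_levels, size=n, p=other_probs)
    disposition = np.where(discharged, "discharged_outpatient", other_draw)

    df = pd.DataFrame(
        {
            "record_id": [f"T{i:07d}" for i in range(1, n + 1)],
            "sender_id": sender,
            "receiver_id": receiver,
            "depart_datetime": depart,
            "arrive_datetime": arrive,
            "age": pd.array(age, dtype="Int64"),
            "sex": sex,
            "reason": reason,
            "condition_category": condition,
            "surgery_at_receiver": pd.array(surgery == "yes", dtype="boolean"),
            "disposition": disposition,
        },
        columns=list(RECORD_COLUMNS),
    )

    ledger = GroundTruthLedger(
        arc_pair_counts=pair_counts,
        per_year_counts=per_year,
        planted_hub_ids=[h.hospital_id for h in registry if h.is_base],
        planted_distributor_ids=distributors,
        planned_in_degrees=planned,
        true_slope=config.target_slope,
        true_reciprocity=true_recip,
        true_discharge_rates=(p_a, p_b),
    )
    return df, ledger


def simulate(
    config: GeneratorConfig | None = None, seed: int | None = None, **overrides
) -> tuple[list[Hospital], pd.DataFrame, GroundTruthLedger]:
    """Convenience wrapper: registry + records + ledger in one call."""
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = GeneratorConfig(**{**config.model_dump(), **overrides})
    base_seed = config.seed if seed is None else seed
    registry = generate_registry(config, seed=base_seed)
    records, ledger = generate_transfers(registry, config, seed=base_seed + 1)
    return registry, records, ledger
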