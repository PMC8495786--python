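"""Survey-effort statistics from vocal events.

Converts the per-species vocal-event database into the quantities used to
compare survey methods:

* independent captures — same-species, same-site events chained while
  consecutive gaps are under one hour, each chain counted once (the
  standard camera-trap independence convention);
* capture rate — independent captures per 1,000 trap-days, computed as
  ``captures / (recording_hours / 24) * 1000`` (a trap-day is 24 h of
  deployed effort);
* detection-effort and cost multipliers between acoustic and camera
  surveys (ratios of total rates and of total cost per capture);
* habitat-averaged relative occurrence frequencies (terra firme and
  floodplain distributions averaged element-wise);
* Pearson chi-square comparison of two frequency distributions;
* eBird checklist filtering and the duration-kernel resampler that draws
  pseudo-checklists from the acoustic capture database with eBird-like
  durations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_LUMP_WINDOW_H = 1.0
HOURS_PER_TRAP_DAY = 24.0


@dataclass
class IndependentCapture:
    species: str
    site_id: str
    habitat: str
    timestamp: pd.Timestamp
    n_lumped_events: int


@dataclass
class EffortTable:
    """Per-species captures, rates and costs for one survey method."""

    method: str  # "acoustic" | "camera"
    table: pd.DataFrame  # columns: species, captures, capture_rate, cost_per_capture

    @property
    def totals(self) -> pd.Series:
        """Column sums over species (the convention for the totals row)."""
        return self.table[["captures", "capture_rate", "cost_per_capture"]].sum()


def lump_independent_captures(events: Sequence, window_h: float = DEFAULT_LUMP_WINDOW_H) -> list[IndependentCapture]:
    """Chain events of one species at one site into independent captures.

    Chronologically per (species, site): an event joins the current chain
    when it starts less than ``window_h`` hours after the previous event
    in that chain (gaps of exactly one hour start a new chain).  Each
    chain becomes one capture timestamped at its first event.
    """
    keyed: dict[tuple[str, str], list] = {}
    for e in events:
        ts = e.timestamp if hasattr(e, "timestamp") else e["timestamp"]
        if ts is None or (isinstance(ts, float) and np.isnan(ts)):
            raise ValueError("event missing absolute timestamp; cannot lump")
        sp = e.species if hasattr(e, "species") else e["species"]
        site = e.site_id if hasattr(e, "site_id") else e["site_id"]
        hab = e.habitat if hasattr(e, "habitat") else e.get("habitat", "")
        keyed.setdefault((sp, site), []).append((pd.Timestamp(ts), hab))
    captures: list[IndependentCapture] = []
    delta = pd.Timedelta(hours=window_h)
    for (sp, site), items in keyed.items():
        items.sort(key=lambda x: x[0])
        chain_start, prev, hab0, n = items[0][0], items[0][0], items[0][1], 1
        for ts, hab in items[1:]:
            if ts - prev < delta:
                prev, n = ts, n + 1
            else:
                captures.append(IndependentCapture(sp, site, hab0, chain_start, n))
                chain_start, prev, hab0, n = ts, ts, hab, 1
        captures.append(IndependentCapture(sp, site, hab0, chain_start, n))
    captures.sort(key=lambda c: (c.species, c.site_id, c.timestamp))
    return captures


def capture_rate(n_captures: float, total_recording_hours: float, per: float = 1000.0) -> float:
    """Captures per ``per`` trap-days of effort (trap-day = 24 h)."""
    if total_recording_hours <= 0:
        raise ValueError("total_recording_hours must be positive")
    return n_captures / (total_recording_hours / HOURS_PER_TRAP_DAY) * per


def effort_table(
    captures_per_species: Mapping[str, int],
    total_recording_hours: float,
    equipment_cost: float | None = None,
    cost_per_capture: Mapping[str, float] | None = None,
    method: str = "acoustic",
) -> EffortTable:
    """Build an effort table from capture counts and survey effort.

    ``cost_per_capture`` may be supplied directly (printed values); else
    it is computed as ``equipment_cost / capture_rate`` per species.
    """
    rows = []
    for sp, n in captures_per_species.items():
        rate = capture_rate(n, total_recording_hours)
        if cost_per_capture is not None:
            cost = cost_per_capture[sp]
        elif equipment_cost is not None:
            if rate == 0:
                log.warning("species %s has zero capture rate; cost undefined", sp)
                cost = np.nan
            else:
                cost = equipment_cost / rate
        else:
            cost = np.nan
        rows.append({"species": sp, "captures": n, "capture_rate": rate, "cost_per_capture": cost})
    return EffortTable(method, pd.DataFrame(rows))


def effort_and_cost(effort_acoustic: EffortTable, effort_camera: EffortTable) -> dict:
    """Compare two survey methods on their shared species set.

    Totals are column sums over the shared species.  The detection-effort
    multiplier is the ratio of total capture rates (acoustic/camera); the
    cost multiplier is the ratio of total cost per capture
    (camera/acoustic).  Multipliers are also reported rounded to integers.
    """
    shared = sorted(set(effort_acoustic.table["species"]) & set(effort_camera.table["species"]))
    if not shared:
        raise ValueError("no shared species between the two effort tables")
    a = effort_acoustic.table.set_index("species").loc[shared]
    c = effort_camera.table.set_index("species").loc[shared]
    rate_a, rate_c = a["capture_rate"].sum(), c["capture_rate"].sum()
    cost_a, cost_c = a["cost_per_capture"].sum(), c["cost_per_capture"].sum()
    if rate_c == 0 or cost_a == 0:
        raise ValueError("zero total rate or cost; multipliers undefined")
    out = {
        "shared_species": shared,
        "total_rate_acoustic": float(rate_a),
        "total_rate_camera": float(rate_c),
        "total_cost_acoustic": float(cost_a),
        "total_cost_camera": float(cost_c),
        "effort_multiplier": float(rate_a / rate_c),
        "cost_multiplier": float(cost_c / cost_a),
    }
    out["effort_multiplier_int"] = int(round(out["effort_multiplier"]))
    out["cost_multiplier_int"] = int(round(out["cost_multiplier"]))
    return out


def habitat_averaged_frequencies(captures: Sequence[IndependentCapture] | pd.DataFrame,
                                 species: Sequence[str] | None = None) -> pd.Series:
    """Species relative frequencies averaged across habitat strata.

    The species distribution is computed separately within each habitat
    (terra firme, floodplain), then averaged element-wise, so each
    habitat contributes equally regardless of its recording effort.
    """
    if isinstance(captures, pd.DataFrame):
        df = captures
    else:
        df = pd.DataFrame([{"species": c.species, "habitat": c.habitat} for c in captures])
    if df.empty:
        raise ValueError("no captures")
    if species is None:
        species = sorted(df["species"].unique())
    habitats = sorted(df["habitat"].unique())
    dists = []
    for hab in habitats:
        sub = df[df["habitat"] == hab]
        if sub.empty:
            raise ValueError(f"habitat stratum {hab!r} has no captures")
        counts = sub["species"].value_counts().reindex(species, fill_value=0).astype(float)
        dists.append(counts / counts.sum())
    return pd.concat(dists, axis=1).mean(axis=1)


def chi_square_compare(freq_observed: Sequence[float], freq_expected: Sequence[float],
                       n_effective: float | None = None) -> tuple[float, float]:
    """Pearson chi-square of observed counts against expected proportions.

    ``freq_observed`` may be counts or proportions; proportions are scaled
    by ``n_effective``.  Expected counts are the comparison distribution
    scaled to the observed total; dof = k - 1.  Zero expected cells are
    pooled into the smallest nonzero cell with a warning.
    """
    obs = np.asarray(freq_observed, dtype=float)
    exp = np.asarray(freq_expected, dtype=float)
    if obs.sum() == 0 or exp.sum() == 0:
        raise ValueError("all-zero input distribution")
    if n_effective is not None:
        obs = obs / obs.sum() * n_effective
    if np.any(exp == 0):
        log.warning("zero expected cells pooled into the last nonzero category")
        keep = exp > 0
        pooled = obs[~keep].sum()
        obs, exp = obs[keep].copy(), exp[keep]
        obs[-1] += pooled
    exp = exp / exp.sum() * obs.sum()
    stat, p = stats.chisquare(obs, exp)
    return float(stat), float(p)


def filter_ebird_checklists(records: pd.DataFrame) -> pd.DataFrame:
    """Constrain eBird checklists to effort comparable with the recorders.

    Keeps stationary checklists with duration <= 150 min and traveling
    checklists with distance <= 0.5 km; other protocols are dropped with
    a warning, and malformed rows are skipped with a count reported.
    """
    required = {"protocol", "duration_min"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"checklist table missing columns: {sorted(missing)}")
    bad = records["duration_min"].isna() | (records["duration_min"] <= 0)
    traveling = records["protocol"] == "traveling"
    if "distance_km" in records.columns:
        bad |= traveling & records["distance_km"].isna()
    else:
        bad |= traveling
    if bad.any():
        log.warning("skipped %d malformed checklist rows", int(bad.sum()))
    df = records[~bad]
    other = ~df["protocol"].isin(["stationary", "traveling"])
    if other.any():
        log.warning("dropped %d checklists with unsupported protocols", int(other.sum()))
        df = df[~other]
    keep_stat = (df["protocol"] == "stationary") & (df["duration_min"] <= 150)
    keep_trav = (df["protocol"] == "traveling") & (df["distance_km"] <= 0.5)
    return df[keep_stat | keep_trav].copy()


def duration_kernel_sample(
    checklists: pd.DataFrame,
    captures: Sequence[IndependentCapture] | pd.DataFrame,
    sessions: pd.DataFrame,
    n_samples: int,
    rng: np.random.Generator,
    species: Sequence[str] | None = None,
    jitter_frac_iqr: float = 0.05,
    max_retries: int = 100,
) -> pd.Series:
    """Estimate per-species occurrence frequencies with eBird-like effort.

    Draws ``n_samples`` pseudo-checklists per habitat: the length is a
    bootstrap resample of the filtered eBird duration distribution with a
    small smoothing jitter (5% of the duration IQR), and the start time is
    uniform within the recorded sessions of that habitat.  A species is
    present when any capture overlaps the sampled period.  Habitat
    frequencies are averaged via :func:`habitat_averaged_frequencies`.

    ``sessions`` columns: site_id, habitat, start (timestamp), duration_s.
    """
    if checklists.empty:
        raise ValueError("no checklists to sample durations from")
    durations = checklists["duration_min"].to_numpy(dtype=float)
    iqr = float(np.subtract(*np.percentile(durations, [75, 25]))) or 1.0
    if isinstance(captures, pd.DataFrame):
        cap_df = captures
    else:
        cap_df = pd.DataFrame(
            [{"species": c.species, "site_id": c.site_id, "habitat": c.habitat,
              "timestamp": c.timestamp} for c in captures]
        )
    if species is None:
        species = sorted(cap_df["species"].unique())
    rows = []
    for hab in sorted(sessions["habitat"].unique()):
        sess = sessions[sessions["habitat"] == hab].reset_index(drop=True)
        for _ in range(n_samples):
            for _try in range(max_retries):
                dur_min = float(rng.choice(durations) + rng.normal(0, jitter_frac_iqr * iqr))
                if dur_min <= 0:
                    continue
                s = sess.iloc[int(rng.integers(len(sess)))]
                start = pd.Timestamp(s["start"]) + pd.Timedelta(
                    seconds=float(rng.uniform(0, max(s["duration_s"], 1e-9))))
                end = start + pd.Timedelta(minutes=dur_min)
                break
            else:
                raise RuntimeError("could not draw a valid pseudo-checklist period")
            here = cap_df[(cap_df["site_id"] == s["site_id"])]
            present = here[(here["timestamp"] >= start) & (here["timestamp"] < end)]
            row = {"habitat": hab}
            for sp in species:
                row[sp] = sp in set(present["species"])
            rows.append(row)
    pseudo = pd.DataFrame(rows)
    # convert presence tables to per-habitat relative frequencies, then average
    dists = []
    for hab, sub in pseudo.groupby("habitat"):
        counts = sub[list(species)].sum().astype(float)
        total = counts.sum()
        dists.append(counts / total if total > 0 else counts)
    return pd.concat(dists, axis=1).mean(axis=1)
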