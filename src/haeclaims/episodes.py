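"""Treatment-episode construction from C1-INH(IV) refill streams.

Intent of use (routine prophylaxis vs on-demand) is not recorded on a
pharmacy claim, so it is inferred from refill patterns: a maximal run of
continuous refills of one intravenous C1-inhibitor brand averaging at least
1500 IU/week and sustained for at least 13 consecutive weeks (91 days) is
classified as a prophylactic episode; a run of the same minimum duration
below that dose rate is on-demand use.  Product labeling recommends 1000 IU
every 3-4 days for prophylaxis, so the slowest recommended schedule averages
1750 IU/week; the 1500 IU/week floor admits slightly individualized regimens.

During a prophylactic episode, any fill of icatibant, ecallantide, or the
*other* C1-INH(IV) brand is a rescue (breakthrough-attack) event.  Fills of
the same brand fold into the prophylaxis refill stream and are never counted
as rescue: same-product on-demand use cannot be separated from refill
activity in claims data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .schema import (
    BERINERT,
    C1INH_IV_PRODUCTS,
    CINRYZE,
    ClaimsDataset,
    SC_PRODUCTS,
)

PROPHYLACTIC = "PROPHYLACTIC"
ON_DEMAND = "ON_DEMAND"
UNCLASSIFIED = "UNCLASSIFIED"

SC_ON_DEMAND = "SC_ON_DEMAND"
DIFFERENT_C1INH = "DIFFERENT_C1INH"


@dataclass(frozen=True)
class EpisodeConfig:
    """Thresholds of the refill-pattern classification rule.

    iu_per_week_threshold : float
        Minimum average weekly dose (IU/week) for assumed prophylaxis.
    min_weeks : int
        Minimum sustained duration, in weeks, for a classifiable episode.
    continuity_gap_days : int
        Maximum gap (days) between successive fills within one continuous
        run.  Prophylactic dosing is every 3-4 days, so 45 days decisively
        breaks continuity.
    terminal_coverage_days : int
        Coverage credited past the last fill when that fill carries no
        days-supply value.
    """

    iu_per_week_threshold: float = 1500.0
    min_weeks: int = 13
    continuity_gap_days: int = 45
    terminal_coverage_days: int = 7

    @property
    def min_days(self) -> int:
        return self.min_weeks * 7


DEFAULT_CONFIG = EpisodeConfig()


@dataclass
class RefillRun:
    """A maximal chain of continuous refills of one product for one patient."""

    patient_id: object
    product: str
    fills: list  # list of (Timestamp, quantity_iu, days_supply or None)
    start_date: pd.Timestamp = field(init=False)
    end_date: pd.Timestamp = field(init=False)

    def __post_init__(self):
        if any(q < 0 for _, q, _ in self.fills):
            raise ValueError("negative fill quantity")
        self.fills = sorted(self.fills, key=lambda f: f[0])
        self.start_date = self.fills[0][0]
        # coverage end: last fill + its days_supply (terminal coverage applied
        # by segment_runs when days_supply is absent)
        last_date, _, last_supply = self.fills[-1]
        self.end_date = last_date + pd.Timedelta(days=int(last_supply))

    @property
    def span_days(self) -> int:
        return (self.end_date - self.start_date).days

    @property
    def total_iu(self) -> float:
        return float(sum(q for _, q, _ in self.fills))


@dataclass
class RescueEvent:
    date: pd.Timestamp
    product: str
    kind: str  # SC_ON_DEMAND or DIFFERENT_C1INH


@dataclass
class TreatmentEpisode:
    run: RefillRun
    avg_weekly_dose: float
    classification: str
    rescue_events: list = field(default_factory=list)

    @property
    def patient_id(self):
        return self.run.patient_id

    @property
    def product(self):
        return self.run.product


def segment_runs(fills, config: EpisodeConfig = DEFAULT_CONFIG) -> list[RefillRun]:
    """Split one patient-product fill list into maximal continuous runs.

    Parameters
    ----------
    fills
        Iterable of ``(patient_id, product, fill_date, quantity_iu,
        days_supply)`` tuples, all for a single patient and product.

    A new run starts whenever the gap between successive fill dates exceeds
    ``config.continuity_gap_days``.  Fills with missing days-supply are
    credited ``config.terminal_coverage_days`` of coverage.
    """
    fills = sorted(fills, key=lambda f: f[2])
    if not fills:
        return []
    patient_id, product = fills[0][0], fills[0][1]
    for f in fills:
        if f[0] != patient_id or f[1] != product:
            raise ValueError("segment_runs expects a single patient-product stream")
        if f[3] is not None and f[3] < 0:
            raise ValueError("negative fill quantity")

    def norm(f):
        _, _, date, qty, supply = f
        if supply is None or pd.isna(supply):
            supply = config.terminal_coverage_days
        return (pd.Timestamp(date), float(qty), int(supply))

    runs, current = [], [norm(fills[0])]
    for f in fills[1:]:
        f = norm(f)
        gap = (f[0] - current[-1][0]).days
        if gap > config.continuity_gap_days:
            runs.append(RefillRun(patient_id, product, current))
            current = [f]
        else:
            current.append(f)
    runs.append(RefillRun(patient_id, product, current))
    return runs


def average_weekly_dose(run: RefillRun) -> float:
    """Average dose rate over the run span: total IU x 7 / span days.

    The span runs from the first fill to the coverage end of the last fill,
    so a schedule of 1000 IU every 4 days (8 fills over days 0-28 with 4-day
    terminal coverage) averages 8000 x 7 / 32 = 1750 IU/week.
    """
    if run.span_days <= 0:
        raise ValueError("run span must be at least 1 day")
    return run.total_iu * 7.0 / run.span_days


def classify_episode(run: RefillRun,
                     config: EpisodeConfig = DEFAULT_CONFIG) -> TreatmentEpisode:
    """Classify one refill run as PROPHYLACTIC / ON_DEMAND / UNCLASSIFIED.

    Runs shorter than 13 weeks (91 days) match neither sustained-use pattern
    and are UNCLASSIFIED; at or above 91 days the 1500 IU/week threshold
    (inclusive) separates prophylactic from on-demand use.
    """
    avg = average_weekly_dose(run)
    if run.span_days < config.min_days:
        cls = UNCLASSIFIED
    elif avg >= config.iu_per_week_threshold:
        cls = PROPHYLACTIC
    else:
        cls = ON_DEMAND
    return TreatmentEpisode(run=run, avg_weekly_dose=avg, classification=cls)


def detect_rescue(episode: TreatmentEpisode, pharmacy: pd.DataFrame) -> TreatmentEpisode:
    """Attach rescue events to a prophylactic episode.

    ``pharmacy`` holds all pharmacy claims of the episode's patient.  Any
    icatibant/ecallantide fill, and any fill of the other C1-INH(IV) brand,
    dated within the episode interval (inclusive) becomes a rescue event.
    """
    if episode.classification != PROPHYLACTIC:
        raise ValueError("rescue detection applies to prophylactic episodes only")
    other_iv = BERINERT if episode.product == CINRYZE else CINRYZE
    events = []
    sub = pharmacy[pharmacy["patient_id"] == episode.patient_id]
    for _, row in sub.sort_values("fill_date").iterrows():
        date = pd.Timestamp(row["fill_date"])
        if not (episode.run.start_date <= date <= episode.run.end_date):
            continue
        if row["product"] in SC_PRODUCTS:
            events.append(RescueEvent(date, row["product"], SC_ON_DEMAND))
        elif row["product"] == other_iv:
            events.append(RescueEvent(date, row["product"], DIFFERENT_C1INH))
    episode.rescue_events = events
    return episode


def build_episodes(dataset: ClaimsDataset,
                   config: EpisodeConfig = DEFAULT_CONFIG) -> list[TreatmentEpisode]:
    """Segment + classify every patient's C1-INH(IV) fills; attach rescue."""
    episodes: list[TreatmentEpisode] = []
    pharm = dataset.pharmacy
    iv = pharm[pharm["product"].isin(C1INH_IV_PRODUCTS)]
    for (pid, product), grp in iv.groupby(["patient_id", "product"], sort=True):
        fills = [
            (pid, product, row["fill_date"], row["quantity_iu"], row["days_supply"])
            for _, row in grp.iterrows()
        ]
        for run in segment_runs(fills, config):
            ep = classify_episode(run, config)
            if ep.classification == PROPHYLACTIC:
                detect_rescue(ep, pharm)
            episodes.append(ep)
    return episodes


def summarize_episodes(episodes) -> dict:
    """Aggregate counts and duration statistics over classified episodes.

    Duration statistics cover prophylactic episodes only; when there are
    none, the stats are reported as None and flagged.
    """
    proph = [e for e in episodes if e.classification == PROPHYLACTIC]
    with_rescue = [e for e in proph if e.rescue_events]
    spans = pd.Series([e.run.span_days for e in proph], dtype=float)
    summary = {
        "n_episodes": len(episodes),
        "n_prophylactic": len(proph),
        "n_on_demand": sum(e.classification == ON_DEMAND for e in episodes),
        "n_unclassified": sum(e.classification == UNCLASSIFIED for e in episodes),
        "n_patients_prophylactic": len({e.patient_id for e in proph}),
        "n_prophylactic_with_rescue": len(with_rescue),
        "pct_prophylactic_with_rescue": (
            round(100.0 * len(with_rescue) / len(proph), 1) if proph else None),
        "duration_defined": bool(proph),
        "duration_mean_days": float(spans.mean()) if proph else None,
        "duration_median_days": float(spans.median()) if proph else None,
        "duration_min_days": int(spans.min()) if proph else None,
        "duration_max_days": int(spans.max()) if proph else None,
    }
    return summary


def episodes_frame(episodes) -> pd.DataFrame:
    """One row per episode, ready for ``episodes.csv``."""
    rows = []
    for e in episodes:
        rows.append({
            "patient_id": e.patient_id,
            "product": e.product,
            "start_date": e.run.start_date,
            "end_date": e.run.end_date,
            "span_days": e.run.span_days,
            "n_fills": len(e.run.fills),
            "total_iu": e.run.total_iu,
            "avg_weekly_dose": e.avg_weekly_dose,
            "classification": e.classification,
            "n_rescue_events": len(e.rescue_events),
        })
    return pd.DataFrame(rows, columns=[
        "patient_id", "product", "start_date", "end_date", "span_days",
        "n_fills", "total_iu", "avg_weekly_dose", "classification",
        "n_rescue_events"])
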