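"""Synthetic administrative-claims generator.

Emulates the structure of a commercial US claims database for a rare-disease
(hereditary angioedema) population: enrollment spans with churn, pharmacy
fills of the four HAE-specific products plus legacy androgens/tranexamic
acid, HAE-coded medical encounters (ICD-9-CM 277.6), port
insertion/removal/complication events, comorbidity diagnoses, and
office/ED/inpatient visits.

Defaults are calibrated to the population the pipeline is designed for:
71% female, ~90% of patients aged 17 to <65, regional and payer mixes of a
commercially insured population, a ~25% prophylaxis uptake, ~5% port
prevalence among intravenous C1-INH users, and a ~56% per-port complication
probability.  Attack-rate and adherence distributions are not identifiable
from published summaries; the defaults are calibration knobs, not estimates
of the real population.

Prophylaxis users receive fill streams constructed to satisfy the episode
rule (1000 IU every 4 days = 1750 IU/week, sustained >= 13 weeks), so the
configured uptake is recoverable by running the episode classifier on the
output.  Identical (config, seed) produce byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    ANDROGEN,
    BERINERT,
    CINRYZE,
    ClaimsDataset,
    ECALLANTIDE,
    ED,
    HAE_DX_CODE,
    ICATIBANT,
    INPATIENT,
    OFFICE,
    OTHER,
)

AGE_BANDS = ("<12", "12-<17", "17-<65", ">=65")
_AGE_RANGES = {"<12": (2, 11), "12-<17": (12, 16), "17-<65": (17, 64), ">=65": (65, 85)}

#: one representative ICD-9-CM code per Deyo category, used when seeding
#: comorbidity diagnoses
COMORBIDITY_CODES = {
    "mi": "410.1", "chf": "428.0", "pvd": "443.9", "cvd": "434.91",
    "dementia": "290.0", "cpd": "493.90", "rheum": "714.0", "pud": "533.9",
    "mild_liver": "571.5", "diabetes": "250.00", "diabetes_compl": "250.40",
    "plegia": "342.90", "renal": "585", "malignancy": "193",
    "severe_liver": "572.2", "mets": "197.7", "aids": "042",
}

DEFAULT_COMORBIDITY_RATES = {
    "cpd": 0.10, "diabetes": 0.06, "rheum": 0.03, "chf": 0.02,
    "mild_liver": 0.02, "malignancy": 0.05, "renal": 0.01,
}


class ConfigError(ValueError):
    """A simulation-config field is invalid; the message names the field."""


@dataclass
class SimConfig:
    n_patients: int = 1000
    seed: int = 0
    study_start: str = "2006-01-01"
    study_end: str = "2014-12-31"
    p_female: float = 0.71
    age_distribution: dict = field(default_factory=lambda: {
        "<12": 0.027, "12-<17": 0.043, "17-<65": 0.895, ">=65": 0.035})
    region_weights: dict = field(default_factory=lambda: {
        "EAST": 0.27, "MIDWEST": 0.265, "SOUTH": 0.395, "WEST": 0.07})
    payer_weights: dict = field(default_factory=lambda: {
        "COMMERCIAL": 0.716, "SELF_INSURED": 0.254, "MEDICAID": 0.021,
        "OTHER": 0.009})
    insurance_weights: dict = field(default_factory=lambda: {
        "PPO": 0.55, "HMO": 0.25, "POS": 0.12, "OTHER": 0.08})
    prophylaxis_uptake: float = 0.25
    mean_attack_rate: float = 6.0       # attacks per patient-year (population mean)
    attack_rate_shape: float = 0.8      # gamma shape of per-patient rates
    p_attack_ed: float = 0.08           # fraction of attacks with an ED claim
    p_attack_hosp: float = 0.02         # fraction with an inpatient stay
    on_demand_product_weights: dict = field(default_factory=lambda: {
        ICATIBANT: 0.5, ECALLANTIDE: 0.1, BERINERT: 0.4})
    p_switch_product: float = 0.1       # per-attack chance of a non-preferred product
    cvad_prevalence: float = 0.054      # among intravenous C1-INH users
    complication_rate: float = 0.556    # per-CVAD probability of >=1 event
    enrollment_churn: float = 0.15      # probability of a mid-span coverage gap
    comorbidity_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_RATES))

    def validate(self) -> "SimConfig":
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise ConfigError("n_patients must be a positive integer")
        start, end = pd.Timestamp(self.study_start), pd.Timestamp(self.study_end)
        if not start < end:
            raise ConfigError("study_start must precede study_end")
        for name in ("p_female", "prophylaxis_uptake", "p_attack_ed",
                     "p_attack_hosp", "cvad_prevalence", "complication_rate",
                     "enrollment_churn"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.mean_attack_rate < 0:
            raise ConfigError("mean_attack_rate must be nonnegative")
        if self.attack_rate_shape <= 0:
            raise ConfigError("attack_rate_shape must be positive")
        if not 0 <= self.p_switch_product <= 1:
            raise ConfigError("p_switch_product must lie in [0, 1]")
        for name in ("age_distribution", "region_weights", "payer_weights",
                     "insurance_weights", "on_demand_product_weights"):
            w = getattr(self, name)
            if any(v < 0 for v in w.values()):
                raise ConfigError(f"{name} has negative weights")
            if abs(sum(w.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name} weights must sum to 1")
        for cat, rate in self.comorbidity_rates.items():
            if cat not in COMORBIDITY_CODES:
                raise ConfigError(f"comorbidity_rates has unknown category {cat!r}")
            if not 0 <= rate <= 1:
                raise ConfigError("comorbidity_rates values must lie in [0, 1]")
        return self


def _choice(rng, weights: dict) -> str:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def generate_cohort(config: SimConfig) -> ClaimsDataset:
    """Draw a full synthetic claims dataset from the configured population."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    total_days = (end - start).days

    patients, enrollment, pharmacy, medical = [], [], [], []

    def med(pid, day, setting, dx1=None, proc1=None):
        medical.append({
            "patient_id": pid, "service_date": day, "dx1": dx1, "dx2": None,
            "dx3": None, "proc1": proc1, "proc2": None, "proc3": None,
            "setting": setting})

    def fill(pid, day, product, iu=None, supply=None):
        pharmacy.append({"patient_id": pid, "fill_date": day,
                         "product": product, "quantity_iu": iu,
                         "days_supply": supply})

    for i in range(config.n_patients):
        pid = f"P{i + 1:06d}"
        band = _choice(rng, config.age_distribution)
        lo, hi = _AGE_RANGES[band]
        age = int(rng.integers(lo, hi + 1))
        patients.append({
            "patient_id": pid,
            "sex": "F" if rng.random() < config.p_female else "M",
            "birth_year": 2010 - age,
            "region": _choice(rng, config.region_weights),
            "payer": _choice(rng, config.payer_weights),
            "insurance_type": _choice(rng, config.insurance_weights),
            "pharmacy_benefit": "Y" if rng.random() < 0.95 else "N",
        })

        # --- enrollment: one long span, sometimes split by a coverage gap
        e_start = start + pd.Timedelta(days=int(rng.integers(0, total_days // 2)))
        duration = 365 + int(rng.exponential(730))
        e_end = min(e_start + pd.Timedelta(days=duration), end)
        spans = [(e_start, e_end)]
        span_days = (e_end - e_start).days
        if rng.random() < config.enrollment_churn and span_days > 400:
            cut = e_start + pd.Timedelta(days=int(rng.integers(150, span_days - 150)))
            gap = int(rng.integers(30, 121))
            if (e_end - cut).days > gap + 30:
                spans = [(e_start, cut), (cut + pd.Timedelta(days=gap + 1), e_end)]
        for s, e in spans:
            enrollment.append({"patient_id": pid, "span_start": s, "span_end": e})
        first_span_start, first_span_end = spans[0]

        # --- first HAE-specific treatment inside the first span
        offset = int(rng.integers(30, 201))
        first_fill = first_span_start + pd.Timedelta(days=offset)
        if first_fill >= first_span_end:
            first_fill = first_span_start + pd.Timedelta(
                days=max(1, (first_span_end - first_span_start).days // 2))

        # HAE diagnosis recorded at the first treatment encounter
        med(pid, first_fill, OFFICE, dx1=HAE_DX_CODE)

        # --- prophylaxis episodes (constructed to satisfy the episode rule)
        is_prophylaxis = rng.random() < config.prophylaxis_uptake
        iv_user = False
        prophylaxis_start = None
        if is_prophylaxis:
            avail = (first_span_end - first_fill).days
            max_fills = avail // 4
            if max_fills >= 23:  # 23 fills x 4 days = 92-day span
                n_fills = int(min(max_fills, 23 + rng.integers(0, 80)))
                for k in range(n_fills):
                    fill(pid, first_fill + pd.Timedelta(days=4 * k),
                         CINRYZE, iu=1000.0, supply=4)
                iv_user = True
                prophylaxis_start = first_fill
                ep_end = first_fill + pd.Timedelta(days=4 * n_fills)
                # occasional second episode after a continuity break
                rest = (first_span_end - ep_end).days
                if rng.random() < 0.3 and rest > 200:
                    gap = int(rng.integers(60, min(180, rest - 100)))
                    start2 = ep_end + pd.Timedelta(days=gap)
                    n2 = int(min((first_span_end - start2).days // 4,
                                 23 + rng.integers(0, 40)))
                    if n2 >= 23:
                        for k in range(n2):
                            fill(pid, start2 + pd.Timedelta(days=4 * k),
                                 CINRYZE, iu=1000.0, supply=4)

        # --- attacks drive on-demand fills and acute-care encounters.
        # Per-patient rates are gamma-heterogeneous (attack frequency is
        # strongly overdispersed across patients) and most patients stick
        # with one preferred on-demand product.
        enrolled_years = sum((e - s).days for s, e in spans) / 365.25
        rate = rng.gamma(config.attack_rate_shape,
                         config.mean_attack_rate / config.attack_rate_shape)
        n_attacks = rng.poisson(rate * enrolled_years)
        attack_window = (first_span_end - first_fill).days
        if not is_prophylaxis and n_attacks == 0:
            n_attacks = 1  # every simulated patient has >=1 treated attack
        preferred = _choice(rng, config.on_demand_product_weights)
        for k in range(int(n_attacks)):
            if k == 0 and not is_prophylaxis:
                # the anchor date is the first treated attack (= index date)
                day = first_fill
            elif attack_window < 1:
                day = first_fill
            else:
                day = first_fill + pd.Timedelta(days=int(rng.integers(0, attack_window)))
            product = preferred
            if rng.random() < config.p_switch_product:
                product = _choice(rng, config.on_demand_product_weights)
            if product == BERINERT:
                fill(pid, day, BERINERT, iu=1500.0, supply=None)
                iv_user = True
            else:
                fill(pid, day, product, iu=None, supply=None)
            if rng.random() < config.p_attack_ed:
                med(pid, day, ED, dx1=HAE_DX_CODE)
            if rng.random() < config.p_attack_hosp:
                stay = int(rng.integers(1, 4))
                for d in range(stay):
                    stay_day = day + pd.Timedelta(days=d)
                    if stay_day <= end:
                        med(pid, stay_day, INPATIENT, dx1=HAE_DX_CODE)

        # legacy therapy noise (never index-eligible)
        if rng.random() < 0.1:
            fill(pid, first_fill + pd.Timedelta(days=int(rng.integers(0, max(1, attack_window)))),
                 ANDROGEN, iu=None, supply=30)

        # --- CVAD among intravenous C1-INH users
        if iv_user and rng.random() < config.cvad_prevalence:
            anchor = prophylaxis_start if prophylaxis_start is not None else first_fill
            insertion = anchor + pd.Timedelta(days=int(rng.integers(0, 4)))
            med(pid, insertion, OTHER, proc1="INSERT_PORT")
            dwell = 40 + int(rng.exponential(200))
            removal = insertion + pd.Timedelta(days=dwell)
            if removal < first_span_end:
                med(pid, removal, OTHER, proc1="REMOVE_PORT")
                port_end = removal
            else:
                port_end = first_span_end
            if rng.random() < config.complication_rate:
                for _ in range(int(rng.integers(1, 3))):
                    span = max(1, (port_end - insertion).days - 10)
                    cday = insertion + pd.Timedelta(days=10 + int(rng.integers(0, span)))
                    u = rng.random()
                    if u < 0.40:
                        med(pid, cday, OTHER, dx1="DX_MECH_COMPL")
                    elif u < 0.75:
                        med(pid, cday, OTHER, proc1="REPLACE_FULL")
                    elif u < 0.90:
                        med(pid, cday, OTHER, dx1="DX_CVC_INFECT_OTHER")
                    else:
                        med(pid, cday, OTHER, dx1="DX_CVC_INFECT_LOCAL")

        # --- baseline comorbidity diagnoses in the pre-index window
        pre_days = (first_fill - first_span_start).days
        for cat, rate in sorted(config.comorbidity_rates.items()):
            if rate > 0 and rng.random() < rate and pre_days >= 2:
                back = int(rng.integers(1, min(170, pre_days)))
                med(pid, first_fill - pd.Timedelta(days=back), OFFICE,
                    dx1=COMORBIDITY_CODES[cat])

        # --- routine office visits
        n_office = rng.poisson(2.0 * enrolled_years)
        for _ in range(int(n_office)):
            s, e = spans[int(rng.integers(0, len(spans)))]
            d = s + pd.Timedelta(days=int(rng.integers(0, max(1, (e - s).days))))
            med(pid, d, OFFICE, dx1="V70.0")

    dataset = ClaimsDataset(
        patients=pd.DataFrame(patients),
        enrollment=pd.DataFrame(enrollment),
        pharmacy=pd.DataFrame(pharmacy).sort_values(
            ["patient_id", "fill_date", "product"], kind="stable").reset_index(drop=True),
        medical=pd.DataFrame(medical).sort_values(
            ["patient_id", "service_date", "setting"], kind="stable").reset_index(drop=True),
    )
    return dataset.validate()
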