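"""Synthetic cohort generator with planted ground truth.

Emulates a case-control pediatric-sepsis plasma-proteomics study measured
on a ~120-protein CNS-focused panel: ``n_control`` healthy controls (one
sample each) and ``n_sepsis`` sepsis subjects sampled on intensive-care
days 1 and 3 (paired).  Abundances are on an arbitrary log2 scale,
log2-normal per protein.  The generator plants, and reports as ground
truth for parameter-recovery testing:

* a subset of differentially expressed proteins (DEPs), shifted by
  ``+/- effect_log2fc`` at D1 vs controls and by an attenuated fraction
  of that shift at D3;
* a set of proteins correlated with the PELOD-2 organ-dysfunction score
  through a shared per-subject severity latent, calibrated so each
  planted protein's population correlation with PELOD-2 equals
  ``rho_outcome``;
* a mortality signal: death is drawn from a logistic model on the
  mortality proteins' standardized D1 values, with the intercept solved
  so the realized marginal death rate matches ``mortality_rate``;
* gene sets in which a few "enriched" terms are seeded predominantly
  (>=70%) with planted DEPs.

Everything is driven by a single integer seed; identical configuration
gives bit-identical matrices, metadata and GMT output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .io_formats import AbundanceMatrix, GeneSetCollection, SampleRecord
import pandas as pd

__all__ = ["SimConfig", "SyntheticTruth", "generate_cohort", "generate_clinical", "generate_gene_sets"]


@dataclass
class SimConfig:
    """Study-design parameters of the simulated cohort.

    Defaults mirror the target study: 23 sepsis subjects with paired
    D1/D3 plasma samples, 23 healthy controls, a 120-protein panel with
    20 planted DEPs at |log2FC| = 1.5 over a residual SD of 0.5.
    """

    n_sepsis: int = 23
    n_control: int = 23
    n_proteins: int = 120
    n_dep: int = 20
    effect_log2fc: float = 1.5
    sd_within: float = 0.5
    d3_attenuation: float = 0.5
    n_outcome_proteins: int = 8
    rho_outcome: float = 0.6
    n_mortality_proteins: int = 5
    mortality_rate: float = 0.15
    n_terms: int = 25
    term_size_range: tuple[int, int] = (8, 30)
    enriched_terms: int = 3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sepsis", "n_control", "n_proteins", "n_terms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_dep", "n_outcome_proteins", "n_mortality_proteins", "enriched_terms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n_dep > self.n_proteins:
            raise ValueError("n_dep cannot exceed n_proteins")
        if self.n_outcome_proteins > self.n_proteins:
            raise ValueError("n_outcome_proteins cannot exceed n_proteins")
        if not 0 < self.mortality_rate < 1:
            raise ValueError(f"mortality_rate must be in (0, 1), got {self.mortality_rate}")
        if not 0 <= self.d3_attenuation <= 1:
            raise ValueError(f"d3_attenuation must be in [0, 1], got {self.d3_attenuation}")
        if not abs(self.rho_outcome) < 1:
            raise ValueError(f"|rho_outcome| must be < 1, got {self.rho_outcome}")
        if self.sd_within <= 0:
            raise ValueError(f"sd_within must be positive, got {self.sd_within}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"term_size_range must satisfy 1 <= lo <= hi, got {self.term_size_range}")
        if hi > self.n_proteins:
            raise ValueError(
                f"term_size_range upper bound {hi} exceeds protein universe of {self.n_proteins}"
            )
        if self.enriched_terms > self.n_terms:
            raise ValueError("enriched_terms cannot exceed n_terms")


@dataclass
class SyntheticTruth:
    """Planted signal: which proteins/terms carry which effect."""

    dep_effects: dict[str, float]  # protein id -> signed log2FC at D1 vs HC
    outcome_ids: list[str]
    mortality_ids: list[str]
    enriched_term_ids: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def dep_ids(self) -> list[str]:
        return list(self.dep_effects)

    def to_dict(self) -> dict:
        return {
            "dep_effects": self.dep_effects,
            "outcome_ids": self.outcome_ids,
            "mortality_ids": self.mortality_ids,
            "enriched_term_ids": self.enriched_term_ids,
            "seed": self.seed,
        }


def _protein_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"PROT{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(config: SimConfig) -> tuple[AbundanceMatrix, list[SampleRecord], SyntheticTruth]:
    """Draw the abundance matrix, sample records and ground truth.

    Sample order is controls first, then sepsis D1, then sepsis D3.
    D3 values reuse the subject's D1 draw plus the attenuation delta and
    fresh noise, giving the within-subject correlation a paired design
    assumes.
    """
    rng = np.random.default_rng(config.seed)
    proteins = _protein_ids(config.n_proteins)
    p = config.n_proteins

    # Per-protein baseline on the log2 scale, drawn once from a wide prior.
    baseline = rng.normal(10.0, 2.0, size=p)

    # Plant DEPs with random signs; outcome and mortality proteins are
    # preferentially drawn from the DEPs so the downstream pathway-clinical
    # graph has a connected planted signal.
    dep_idx = rng.choice(p, size=config.n_dep, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_dep)
    dep_effects = {proteins[i]: float(s * config.effect_log2fc) for i, s in zip(dep_idx, signs)}

    def _pick(n_pick: int, pool_first: np.ndarray) -> list[int]:
        pool = list(pool_first)
        rest = [i for i in range(p) if i not in set(pool)]
        take = pool[:n_pick]
        if len(take) < n_pick:
            extra = rng.choice(len(rest), size=n_pick - len(take), replace=False)
            take = take + [rest[j] for j in extra]
        return take

    shuffled_dep = rng.permutation(dep_idx)
    outcome_idx = _pick(config.n_outcome_proteins, shuffled_dep)
    mortality_idx = _pick(config.n_mortality_proteins, rng.permutation(dep_idx))

    n_hc, n_sep = config.n_control, config.n_sepsis
    hc_ids = [f"HC{i:03d}" for i in range(1, n_hc + 1)]
    subjects = [f"SEP{i:03d}" for i in range(1, n_sep + 1)]

    effect = np.zeros(p)
    for i, s in zip(dep_idx, signs):
        effect[i] = s * config.effect_log2fc

    sd = config.sd_within
    hc_vals = baseline + rng.normal(0.0, sd, size=(n_hc, p))

    # Severity latent per sepsis subject and day; shared across the planted
    # outcome proteins so each can reach a per-protein correlation of
    # rho_outcome with PELOD-2 (impossible with independent proteins for
    # more than ~1/rho^2 of them).
    rho = abs(config.rho_outcome)
    lam = np.sqrt(rho)
    latent_d1 = rng.normal(0.0, 1.0, size=n_sep)
    latent_d3 = 0.5 * latent_d1 + np.sqrt(0.75) * rng.normal(0.0, 1.0, size=n_sep)

    def _sepsis_noise(latent: np.ndarray) -> np.ndarray:
        eps = rng.normal(0.0, 1.0, size=(n_sep, p))
        z = eps.copy()
        if rho > 0 and outcome_idx:
            z[:, outcome_idx] = lam * latent[:, None] + np.sqrt(1 - lam**2) * eps[:, outcome_idx]
        return sd * z

    d1_noise = _sepsis_noise(latent_d1)
    d1_vals = baseline + effect + d1_noise
    # D3 = subject's D1 value + attenuation delta + fresh noise.
    d3_delta = effect * (config.d3_attenuation - 1.0)
    d3_vals = d1_vals + d3_delta + _sepsis_noise(latent_d3)

    values = np.vstack([hc_vals, d1_vals, d3_vals])
    sample_ids = hc_ids + [f"{s}_D1" for s in subjects] + [f"{s}_D3" for s in subjects]
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = AbundanceMatrix(pd.DataFrame(values, index=sample_ids, columns=proteins))

    records = [
        SampleRecord(sample_id=sid, subject_id=sid, group="HC", timepoint="NA") for sid in hc_ids
    ]
    for tp in ("D1", "D3"):
        records += [
            SampleRecord(sample_id=f"{s}_{tp}", subject_id=s, group="SEPSIS", timepoint=tp)
            for s in subjects
        ]

    truth = SyntheticTruth(
        dep_effects=dep_effects,
        outcome_ids=[proteins[i] for i in outcome_idx],
        mortality_ids=[proteins[i] for i in mortality_idx],
        seed=config.seed,
    )
    return matrix, records, truth


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sdev = x.std(axis=0, ddof=0)
    sdev[sdev == 0] = 1.0
    return (x - mu) / sdev


def generate_clinical(
    truth: SyntheticTruth,
    records: list[SampleRecord],
    config: SimConfig,
    matrix: AbundanceMatrix,
) -> list[SampleRecord]:
    """Attach clinical variables to the sample records (in place, returned).

    PELOD-2 per day is ``a * mean(standardized planted values) + noise``
    with ``a`` calibrated so each planted protein's population correlation
    is ``rho_outcome``; mortality is a per-subject Bernoulli draw from a
    logistic model on the planted mortality proteins, with the intercept
    solved so the realized marginal death probability equals
    ``mortality_rate``.  Healthy controls carry no severity scores.
    Demographics and comorbidity/support flags are nuisance variables with
    no planted protein signal.
    """
    by_id = {r.sample_id: r for r in records}
    for sid in matrix.sample_ids:
        if sid not in by_id:
            raise ValueError(f"sample {sid!r} in matrix but not in records")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))

    sep_records = {
        tp: [r for r in records if r.group == "SEPSIS" and r.timepoint == tp] for tp in ("D1", "D3")
    }
    n_sep = len(sep_records["D1"])
    if {r.subject_id for r in sep_records["D1"]} != {r.subject_id for r in sep_records["D3"]}:
        raise ValueError("D1 and D3 sepsis records do not cover the same subjects")

    rho = config.rho_outcome
    pelod_by_subject: dict[tuple[str, str], float] = {}
    for tp in ("D1", "D3"):
        recs = sorted(sep_records[tp], key=lambda r: r.subject_id)
        sids = [r.sample_id for r in recs]
        if truth.outcome_ids and rho != 0:
            x = matrix.values_for(sids)[truth.outcome_ids].to_numpy()
            z = _standardize_columns(x)
            score = z.mean(axis=1)
            score = score / max(score.std(ddof=0), 1e-12)
            p_eff = len(truth.outcome_ids)
            # corr(protein_i, score) ~ sqrt(rho + (1-rho)/p); scale so the
            # per-protein correlation with PELOD-2 lands on rho_outcome.
            base_corr = np.sqrt(abs(rho) + (1 - abs(rho)) / p_eff)
            a = min(abs(rho) / base_corr, 1.0) * np.sign(rho)
        else:
            score = np.zeros(n_sep)
            a = 0.0
        noise = rng.normal(0.0, 1.0, size=n_sep)
        latent = a * score + np.sqrt(max(1 - a**2, 0.0)) * noise
        # Map the unit-scale latent onto a plausible integer PELOD-2 range.
        pelod = np.clip(np.rint(6.0 + 3.0 * latent), 0, 33)
        for r, v in zip(recs, pelod):
            pelod_by_subject[(r.subject_id, tp)] = float(v)

    # Mortality from a logistic model on D1 mortality-protein values.
    d1_recs = sorted(sep_records["D1"], key=lambda r: r.subject_id)
    d1_sids = [r.sample_id for r in d1_recs]
    if truth.mortality_ids:
        xm = matrix.values_for(d1_sids)[truth.mortality_ids].to_numpy()
        risk = _standardize_columns(xm).mean(axis=1)
        risk = risk / max(risk.std(ddof=0), 1e-12)
    else:
        risk = np.zeros(n_sep)
    slope = 1.5

    def marginal(b0: float) -> float:
        return float(np.mean(expit(b0 + slope * risk))) - config.mortality_rate

    b0 = brentq(marginal, -50.0, 50.0)
    death = (rng.random(n_sep) < expit(b0 + slope * risk)).astype(int)
    mortality = {r.subject_id: int(d) for r, d in zip(d1_recs, death)}

    subjects = sorted({r.subject_id for r in records})
    sexes = {s: ("M" if rng.random() < 0.5 else "F") for s in subjects}
    ages = {s: float(np.round(rng.uniform(0.5, 17.0), 1)) for s in subjects}

    sep_subjects = sorted({r.subject_id for r in sep_records["D1"]})
    comorbidity = {s: int(rng.random() < 0.9) for s in sep_subjects}
    neuro = {s: int(comorbidity[s] and rng.random() < 0.33) for s in sep_subjects}
    sources = ["respiratory", "abdominal", "urinary", "bloodstream", "wound", "other"]
    source = {s: sources[rng.choice(len(sources), p=[0.48, 0.13, 0.1, 0.13, 0.06, 0.1])] for s in sep_subjects}
    mech_vent = {s: int(rng.random() < 0.74) for s in sep_subjects}
    circ_support = {s: int(rng.random() < 0.83) for s in sep_subjects}
    picu_days = {s: float(np.rint(np.clip(rng.lognormal(np.log(9.0), 0.5), 3, 60))) for s in sep_subjects}
    hosp_days = {s: float(np.rint(np.clip(picu_days[s] + rng.lognormal(np.log(8.0), 0.6), 4, 120))) for s in sep_subjects}

    for r in records:
        r.clinical["sex"] = sexes[r.subject_id]
        r.clinical["age_years"] = ages[r.subject_id]
        if r.group == "SEPSIS":
            s = r.subject_id
            r.clinical["PELOD2_D1"] = pelod_by_subject[(s, "D1")]
            r.clinical["PELOD2_D3"] = pelod_by_subject[(s, "D3")]
            r.clinical["mortality"] = mortality[s]
            r.clinical["comorbidity"] = comorbidity[s]
            r.clinical["neuro_comorbidity"] = neuro[s]
            r.clinical["infection_source"] = source[s]
            r.clinical["mech_ventilation"] = mech_vent[s]
            r.clinical["circ_support"] = circ_support[s]
            r.clinical["picu_days"] = picu_days[s]
            r.clinical["hospital_days"] = hosp_days[s]
        else:
            for key in ("PELOD2_D1", "PELOD2_D3", "mortality"):
                r.clinical[key] = np.nan
    return records


def generate_gene_sets(config: SimConfig, truth: SyntheticTruth) -> GeneSetCollection:
    """Draw gene sets over the protein universe, seeding enriched terms with DEPs.

    Enriched terms draw at least 70% of their members from the planted
    DEPs; the remaining terms sample the universe uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    universe = _protein_ids(config.n_proteins)
    dep_ids = [pid for pid in universe if pid in truth.dep_effects]
    non_dep = [pid for pid in universe if pid not in truth.dep_effects]
    lo, hi = config.term_size_range
    terms = []
    width = max(2, len(str(config.n_terms)))
    for t in range(config.n_terms):
        tid = f"TERM{t + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if t < config.enriched_terms and dep_ids:
            # cap size so the planted-DEP fraction of >=70% stays feasible
            size = max(min(size, int(np.floor(len(dep_ids) / 0.7))), 1)
            n_from_dep = min(len(dep_ids), max(int(np.ceil(0.7 * size)), 1))
            n_rest = size - n_from_dep
            chosen = [dep_ids[i] for i in rng.choice(len(dep_ids), size=n_from_dep, replace=False)]
            if n_rest > 0:
                pool = non_dep if len(non_dep) >= n_rest else [p for p in universe if p not in chosen]
                chosen += [pool[i] for i in rng.choice(len(pool), size=n_rest, replace=False)]
            desc = "planted enriched set"
        else:
            chosen = [universe[i] for i in rng.choice(len(universe), size=size, replace=False)]
            desc = "background set"
        # Preserve universe order for byte-stable GMT output.
        order = {p: i for i, p in enumerate(universe)}
        chosen = sorted(set(chosen), key=order.__getitem__)
        terms.append((tid, desc, chosen))
    truth.enriched_term_ids = [terms[t][0] for t in range(min(config.enriched_terms, len(terms)))]
    return GeneSetCollection(terms)


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["term_size_range"] = list(config.term_size_range)
    return d
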