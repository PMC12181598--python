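"""Synthetic cohort, expression, serum and knowledge-base generation.

The generator emulates the data structure of a biomarker-discovery study in
older adults: a cohort of fit and pre-frail participants (75+ years) of both
sexes with three timed lower-body function tests (400-m walk capped at 900 s,
4-m gait, five-chair-stand), young reference groups without function tests,
a normalized muscle gene-expression matrix with *planted* gene–phenotype
correlations of known strength, a serum-marker table with sex-specific
fitness effects, and a mock biomarker knowledge base with saved ground truth.

A single latent "slowness" factor per old participant (higher = worse
performance) drives all three test times, the planted expression markers and
the serum effects, so every downstream stage sees internally consistent
signal with a known answer.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TEST_NAMES = ("walk400", "gait4", "chair5")
SEXES = ("F", "M")

# Timed-test marginals for the old groups: (mean, SD) seconds per sex,
# log-normal moment-matched.  SDs derived from reported SEMs at the
# reference group sizes (24 F / 28 M).
TEST_MARGINALS = {
    "walk400": {"F": (351.7, 55.4), "M": (323.3, 40.2)},
    "gait4": {"F": (4.2, 1.0), "M": (3.9, 1.1)},
    "chair5": {"F": (14.3, 4.4), "M": (13.3, 3.7)},
}

AGE_MARGINALS = {"old": (79.8, 3.0), "young": (23.0, 1.8)}
BMI_MARGINALS = {"old": (26.2, 3.2), "young": (22.4, 1.5)}
# Fried frailty score distribution: ~44% pre-frail (score 1-2), rest fit.
FRIED_PROBS = (0.56, 0.30, 0.14)

# Expected gap between adjacent tertile means of a standard normal
# (E[Z | middle third] = 0, outer thirds = ∓(3/√(2π))·e^{-z₃³·...} ≈ ∓1.0908).
_TERTILE_GAP = 1.0908


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration field is invalid."""


@dataclass(frozen=True)
class PlantedMarker:
    """A gene planted to correlate with one test in one sex at known strength."""

    gene_id: str
    sex: str
    test: str
    target_r: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"PlantedMarker.sex must be F or M, got {self.sex!r}")
        if self.test not in TEST_NAMES:
            raise ConfigurationError(f"PlantedMarker.test must be one of {TEST_NAMES}, got {self.test!r}")
        if not abs(self.target_r) < 1:
            raise ConfigurationError(f"PlantedMarker.target_r must satisfy |r| < 1, got {self.target_r}")


@dataclass(frozen=True)
class SerumSpec:
    """Specification of one simulated serum marker.

    ``standardized_shift_per_tertile`` is the expected difference, in SD
    units of the marker, between adjacent fitness tertiles of the targeted
    sex's old group (positive = higher concentration in slower tertiles).
    ``old_young_shift`` is the old-minus-young difference in SD units.
    """

    marker_name: str
    sex_effect: str = "none"
    standardized_shift_per_tertile: float = 0.0
    old_young_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.sex_effect not in {"F", "M", "both", "none"}:
            raise ConfigurationError(
                f"SerumSpec.sex_effect must be F, M, both or none, got {self.sex_effect!r}"
            )


@dataclass(frozen=True)
class KBComposition:
    """Field-frequency recipe for the mock biomarker knowledge base.

    Each gene receives a Poisson-distributed number of records; every record
    draws one value per scalar facet and a random subset per multi-valued
    facet from the given (value -> probability) tables.  ``force_qualify``
    lists genes that always receive one record matching ``truth_criteria``.
    """

    mean_records_per_gene: float = 1.0
    population: dict = field(
        default_factory=lambda: {"All": 0.25, "Adult": 0.35, "Pediatric": 0.40}
    )
    sample_type: dict = field(
        default_factory=lambda: {"Serum": 0.30, "Plasma": 0.20, "Urine": 0.25, "Tissue": 0.25}
    )
    validity: dict = field(
        default_factory=lambda: {
            "Early studies in humans": 0.35,
            "Late studies in humans": 0.15,
            "Recommended/Approved": 0.10,
            "Preclinical": 0.40,
        }
    )
    conditions: dict = field(
        default_factory=lambda: {
            "Sarcopenia": 0.10,
            "Muscle wasting": 0.10,
            "Metabolic syndrome": 0.15,
            "Insulin resistance": 0.10,
            "Oxidative stress": 0.10,
            "Cancer": 0.25,
            "Cardiovascular disease": 0.20,
        }
    )
    roles: dict = field(
        default_factory=lambda: {
            "(Differential) Diagnosis": 0.20,
            "Prognosis (- risk stratification)": 0.15,
            "Monitoring disease progression": 0.15,
            "Risk factor": 0.15,
            "Not specified": 0.35,
        }
    )
    mean_conditions_per_record: float = 1.5
    mean_roles_per_record: float = 1.2
    force_qualify: tuple = ()


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort."""

    n_old_female: int = 24
    n_old_male: int = 28
    n_young_female: int = 13
    n_young_male: int = 13
    n_genes: int = 2000
    planted_markers: tuple = ()
    walk_cap_seconds: float = 900.0
    test_correlation: float = 0.6  # latent-factor pairwise correlation of the three tests
    serum_markers: tuple = ()
    kb_composition: KBComposition = field(default_factory=KBComposition)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_old_female", "n_old_male", "n_young_female", "n_young_male", "n_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"SimConfig.{name} must be a non-negative integer, got {v!r}")
        if self.walk_cap_seconds <= 0:
            raise ConfigurationError("SimConfig.walk_cap_seconds must be positive")
        if not 0 <= self.test_correlation < 1:
            raise ConfigurationError("SimConfig.test_correlation must lie in [0, 1)")
        object.__setattr__(self, "planted_markers", tuple(self.planted_markers))
        object.__setattr__(self, "serum_markers", tuple(self.serum_markers))
        planted_genes = {m.gene_id for m in self.planted_markers}
        if self.n_genes < len(planted_genes):
            raise ConfigurationError(
                f"SimConfig.n_genes={self.n_genes} smaller than {len(planted_genes)} distinct planted genes"
            )

    def gene_ids(self) -> list[str]:
        """Gene universe: planted ids first, then filler ids."""
        planted = sorted({m.gene_id for m in self.planted_markers})
        filler = [f"G{i:05d}" for i in range(self.n_genes)]
        out = list(planted)
        for g in filler:
            if len(out) == self.n_genes:
                break
            if g not in set(planted):
                out.append(g)
        return sorted(out)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Independent per-table generator derived from the config seed.

    Stream names are hashed with crc32 (stable across processes, unlike
    Python's salted str hash) so each table is reproducible on its own.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(zlib.crc32(stream.encode()),))
    return np.random.default_rng(ss)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2, math.sqrt(sigma2)


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate the participant table.

    Returns a DataFrame indexed by ``sample_id`` with columns sex, age_group,
    age, bmi, fried_score, latent_slowness and the three test times (NaN for
    young participants).  Old participants' test times share a latent
    slowness factor; 400-m walk times above the cap are set to the cap.
    """
    rng = _rng(config, "cohort")
    rows = []
    groups = [
        ("F", "old", config.n_old_female),
        ("M", "old", config.n_old_male),
        ("F", "young", config.n_young_female),
        ("M", "young", config.n_young_male),
    ]
    rho = config.test_correlation
    for sex, age_group, n in groups:
        for i in range(n):
            sid = f"{sex}{age_group[0].upper()}{i + 1:03d}"
            age_m, age_s = AGE_MARGINALS[age_group]
            bmi_m, bmi_s = BMI_MARGINALS[age_group]
            row = {
                "sample_id": sid,
                "sex": sex,
                "age_group": age_group,
                "age": round(float(rng.normal(age_m, age_s)), 1),
                "bmi": round(float(rng.normal(bmi_m, bmi_s)), 1),
                "fried_score": int(rng.choice(3, p=FRIED_PROBS)),
                "latent_slowness": np.nan,
                "walk400": np.nan,
                "gait4": np.nan,
                "chair5": np.nan,
            }
            if age_group == "old":
                z = float(rng.normal())  # shared slowness factor, higher = slower
                row["latent_slowness"] = z
                for test in TEST_NAMES:
                    mean, sd = TEST_MARGINALS[test][sex]
                    mu, sigma = _lognormal_params(mean, sd)
                    e = math.sqrt(rho) * z + math.sqrt(1 - rho) * float(rng.normal())
                    t = math.exp(mu + sigma * e)
                    if test == "walk400":
                        t = min(t, config.walk_cap_seconds)
                    row[test] = t
            rows.append(row)
    cols = [
        "sample_id", "sex", "age_group", "age", "bmi", "fried_score",
        "latent_slowness", "walk400", "gait4", "chair5",
    ]
    cohort = pd.DataFrame(rows, columns=cols)
    return cohort.set_index("sample_id")


def generate_expression(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Generate the normalized expression matrix (genes x samples).

    Planted markers follow ``a·z + ε`` within the targeted sex's old
    participants, where ``z`` is the standardized test time of the planted
    test, ``a = r/sqrt(1−r²)`` and ``ε`` is unit-variance noise, so the
    population correlation equals ``target_r``.  All other gene/sample cells
    are independent noise around a gene-specific baseline.
    """
    rng = _rng(config, "expression")
    gene_ids = config.gene_ids()
    n_samples = len(cohort)
    baselines = rng.normal(6.0, 1.5, size=len(gene_ids))
    X = rng.normal(0.0, 1.0, size=(len(gene_ids), n_samples)) + baselines[:, None]
    expr = pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"), columns=cohort.index)

    for marker in config.planted_markers:
        if marker.gene_id not in expr.index:
            raise ConfigurationError(f"planted gene {marker.gene_id!r} not among generated gene ids")
        mask = (cohort["sex"] == marker.sex) & (cohort["age_group"] == "old")
        times = cohort.loc[mask, marker.test].dropna()
        if len(times) == 0:
            continue
        if len(times) < 3:
            raise ConfigurationError(
                f"planted marker {marker.gene_id!r} needs >=3 old {marker.sex} participants"
            )
        z = (times - times.mean()) / times.std(ddof=0)
        a = marker.target_r / math.sqrt(1 - marker.target_r**2)
        eps = rng.normal(size=len(times))
        expr.loc[marker.gene_id, times.index] = (
            float(expr.loc[marker.gene_id].mean()) + a * z.to_numpy() + eps
        )
    return expr


def generate_serum(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Generate the serum concentration table (samples x markers), all values positive.

    Targeted markers shift along the latent slowness factor within the
    targeted sex's old group by ``standardized_shift_per_tertile`` per
    fitness tertile; ``old_young_shift`` separates age groups.  Values are
    log-normal around a marker baseline.
    """
    rng = _rng(config, "serum")
    data = {}
    is_old = (cohort["age_group"] == "old").to_numpy()
    z = cohort["latent_slowness"].fillna(0.0).to_numpy()
    for spec in config.serum_markers:
        target = np.zeros(len(cohort))
        if spec.sex_effect != "none":
            sexes = {"both": ("F", "M")}.get(spec.sex_effect, (spec.sex_effect,))
            sex_mask = cohort["sex"].isin(sexes).to_numpy() & is_old
            target[sex_mask] = (spec.standardized_shift_per_tertile / _TERTILE_GAP) * z[sex_mask]
        target += spec.old_young_shift * is_old
        raw = target + rng.normal(size=len(cohort))
        # 0.25 log-SD keeps concentrations positive with realistic ~25% CV
        data[spec.marker_name] = 100.0 * np.exp(0.25 * raw)
    return pd.DataFrame(data, index=cohort.index)


def _draw_subset(rng: np.random.Generator, freqs: dict, mean_k: float) -> list[str]:
    values = sorted(freqs)
    p = np.array([freqs[v] for v in values], dtype=float)
    p = p / p.sum()
    k = min(len(values), max(1, rng.poisson(mean_k)))
    return sorted(rng.choice(values, size=k, replace=False, p=p))


def generate_knowledge_base(gene_ids: list[str], config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate the mock biomarker knowledge base and its ground truth.

    Returns ``(records, ground_truth)``.  ``records`` has one row per record
    with columns gene_symbol, population, sample_type, validity, conditions,
    roles (multi-valued fields '|'-joined).  ``ground_truth`` holds the
    described/qualified gene counts under the composition's reference
    criteria, recounted record-by-record with a plain loop independent of
    the selection module.
    """
    if not gene_ids:
        raise ConfigurationError("generate_knowledge_base requires a non-empty gene_ids list")
    rng = _rng(config, "knowledge_base")
    comp = config.kb_composition
    rows = []
    for gene in gene_ids:
        for _ in range(rng.poisson(comp.mean_records_per_gene)):
            rows.append(
                {
                    "gene_symbol": gene,
                    "population": _draw_subset(rng, comp.population, 1.0)[0],
                    "sample_type": _draw_subset(rng, comp.sample_type, 1.0)[0],
                    "validity": _draw_subset(rng, comp.validity, 1.0)[0],
                    "conditions": "|".join(
                        _draw_subset(rng, comp.conditions, comp.mean_conditions_per_record)
                    ),
                    "roles": "|".join(_draw_subset(rng, comp.roles, comp.mean_roles_per_record)),
                }
            )
    truth = reference_criteria()
    for gene in comp.force_qualify:
        if gene in set(gene_ids):
            rows.append(
                {
                    "gene_symbol": gene,
                    "population": "Adult",
                    "sample_type": "Serum",
                    "validity": "Early studies in humans",
                    "conditions": "Sarcopenia",
                    "roles": "(Differential) Diagnosis",
                }
            )
    kb = pd.DataFrame(
        rows,
        columns=["gene_symbol", "population", "sample_type", "validity", "conditions", "roles"],
    )

    # Ground-truth recount: naive per-record loop, kept independent of the
    # vectorised filter in frailmark.selection.
    described, qualified = set(), set()
    for _, rec in kb.iterrows():
        described.add(rec["gene_symbol"])
        conds = set(rec["conditions"].split("|")) if rec["conditions"] else set()
        roles = set(rec["roles"].split("|")) if rec["roles"] else set()
        if (
            rec["population"] in truth["population"]
            and rec["sample_type"] in truth["sample_type"]
            and rec["validity"] in truth["validity"]
            and conds & set(truth["conditions"])
            and roles & set(truth["roles"])
        ):
            qualified.add(rec["gene_symbol"])
    ground_truth = {
        "criteria": truth,
        "n_records": int(len(kb)),
        "described_genes": sorted(described),
        "qualified_genes": sorted(qualified),
        "n_described": len(described),
        "n_qualified": len(qualified),
    }
    return kb, ground_truth


def reference_criteria() -> dict:
    """The filter vocabulary used by the study-style funnel (also the mock KB truth criteria)."""
    return {
        "population": ["All", "Adult"],
        "sample_type": ["Serum", "Plasma"],
        "validity": ["Early studies in humans", "Late studies in humans", "Recommended/Approved"],
        "conditions": [
            "Sarcopenia", "Muscle wasting", "Muscular atrophy", "Generalized weakness",
            "Oxidative stress", "Metabolic syndrome", "Insulin resistance", "Muscle disorders",
            "Nerve and muscle disorders", "Calcium metabolism disorders", "Vitamin D deficiency",
            "Inborn errors of metabolism",
        ],
        "roles": [
            "(Differential) Diagnosis", "Disease profiling", "Monitoring disease progression",
            "Monitoring treatment efficacy", "Predicting treatment efficacy",
            "Prognosis (- risk stratification)", "Risk factor", "Selection for therapy",
        ],
    }


def generate_gene_sets(gene_ids: list[str], config: SimConfig, n_terms: int = 53) -> dict:
    """Mock GO-style gene-set collection: term_id -> (term_name, member set).

    Terms draw random memberships covering roughly 60% of the gene universe;
    every planted marker gene is guaranteed membership in at least one term
    so the downstream funnel retains the ground truth.
    """
    rng = _rng(config, "gene_sets")
    universe = np.array(sorted(gene_ids))
    n_cover = max(1, int(0.6 * len(universe)))
    covered = rng.choice(universe, size=n_cover, replace=False)
    sets = {}
    for t in range(n_terms):
        term_id = f"GO:{7000000 + t}"
        size = max(3, rng.poisson(max(3, len(covered) // max(1, n_terms // 2))))
        members = set(rng.choice(covered, size=min(size, len(covered)), replace=False))
        sets[term_id] = (f"mock biological process {t}", members)
    planted = sorted({m.gene_id for m in config.planted_markers})
    if planted and sets:
        first = next(iter(sets))
        name, members = sets[first]
        sets[first] = (name, members | set(planted))
    return sets


def write_outputs(outdir: str | Path, config: SimConfig) -> dict:
    """Generate all tables and write them as TSV/GMT/JSON under ``outdir``.

    Returns a dict of the written paths plus the in-memory tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    expr = generate_expression(cohort, config)
    serum = generate_serum(cohort, config)
    kb, truth = generate_knowledge_base(config.gene_ids(), config)
    gene_sets = generate_gene_sets(config.gene_ids(), config)

    cohort_path = outdir / "cohort.tsv"
    cohort.reset_index().to_csv(cohort_path, sep="\t", index=False)
    expr_path = outdir / "expression.tsv"
    expr.reset_index().to_csv(expr_path, sep="\t", index=False)
    serum_path = outdir / "serum.tsv"
    serum.reset_index().rename(columns={"index": "sample_id"}).to_csv(serum_path, sep="\t", index=False)
    kb_path = outdir / "knowledge_base.tsv"
    kb.to_csv(kb_path, sep="\t", index=False)
    gmt_path = outdir / "gene_sets.gmt"
    with open(gmt_path, "w") as fh:
        for term_id, (name, members) in gene_sets.items():
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")
    truth_path = outdir / "ground_truth.json"
    truth_payload = {
        "planted_markers": [dataclasses.asdict(m) for m in config.planted_markers],
        "serum_markers": [dataclasses.asdict(s) for s in config.serum_markers],
        "knowledge_base": truth,
    }
    with open(truth_path, "w") as fh:
        json.dump(truth_payload, fh, indent=2, sort_keys=True)
    return {
        "cohort": cohort, "expression": expr, "serum": serum, "knowledge_base": kb,
        "gene_sets": gene_sets, "ground_truth": truth_payload,
        "paths": {
            "cohort": cohort_path, "expression": expr_path, "serum": serum_path,
            "knowledge_base": kb_path, "gmt": gmt_path, "ground_truth": truth_path,
        },
    }
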