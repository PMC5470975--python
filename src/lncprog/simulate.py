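"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a bulk microarray study of B-cell differentiation and
lymphoma: five normal stages plus a tumor group on the log2 scale, one
planted prognostic lncRNA (down-shifted in tumor, higher in the GCB
subtype), latent-factor co-expression modules planted in the tumor samples,
a trio of coding partner genes tightly coupled to the biomarker,
exponential survival with a known hazard ratio between the biomarker's
mean-split strata and calibrated right-censoring, and GO-style term sets
(one planted term per module plus size-matched decoys).

Within-module correlation is induced by a single latent factor per module
with loading λ = σ·√(ρ/(1−ρ)), which gives the closed form
λ²/(λ²+σ²) = ρ used by the calibration tests.  Every output is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import DomainError
from .io import GeneCatalog, write_biotype_table, write_expression_matrix, write_gmt, write_sample_sheet
from .survival import mean_split

STAGES = ("naive B cells", "centroblasts", "centrocytes", "memory B cells", "plasma cells")
TUMOR_GROUP = "DLBCL"


@dataclass
class SyntheticConfig:
    """Study-design parameters; defaults mirror the emulated cohorts.

    Five normal stages of 5 samples each and a 170-patient tumor cohort, a
    biomarker down-shift of 2 log2 units in tumor with a 0.5-unit GCB
    subtype lift, three 35-gene modules (30 coding + 5 lncRNA) at
    within-module correlation 0.8, a planted hazard ratio of 1.7 between
    mean-split strata with ~30% censoring, and a 70:100 GCB:non-GCB margin.
    """

    seed: int = 0
    n_per_stage: int = 5
    n_tumor: int = 170
    n_coding: int = 300
    n_lnc: int = 60
    n_modules: int = 3
    coding_per_module: int = 30
    lnc_per_module: int = 5
    module_rho: float = 0.8
    noise_sd: float = 0.5
    biomarker_delta: float = 2.0
    subtype_delta: float = 0.5
    #: latent-factor loading of the biomarker on its module (log2 units);
    #: kept below the full module loading so its tumor variance stays near the
    #: noise scale (keeping the tumor-vs-stage contrast detectable) while the
    #: within-tumor correlation with module members (~0.5 at the defaults)
    #: still clears the Bonferroni edge threshold at the 170-sample cohort
    biomarker_loading: float = 0.4
    trio_size: int = 3
    trio_rho: float = 0.95
    hazard_ratio: float = 1.7
    baseline_median_months: float = 78.0
    censoring_fraction: float = 0.3
    gcb_fraction: float = 70.0 / 170.0
    n_decoy_terms: int = 20

    def __post_init__(self) -> None:
        if min(self.n_per_stage, self.n_tumor, self.n_coding, self.n_lnc) <= 0:
            raise DomainError("all sizes must be positive")
        if not 0 <= self.module_rho < 1:
            raise DomainError("module_rho must lie in [0, 1)")
        if not 0 <= self.censoring_fraction < 1:
            raise DomainError("censoring fraction must lie in [0, 1)")
        if self.hazard_ratio <= 0:
            raise DomainError("hazard ratio must be positive")
        if self.n_modules * self.coding_per_module > self.n_coding:
            raise DomainError("module coding sizes exceed n_coding")
        if self.n_modules * self.lnc_per_module > self.n_lnc:
            raise DomainError("module lncRNA sizes exceed n_lnc")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth backing the recovery tests."""

    biomarker: str
    trio: list[str]
    module_of: dict[str, str]  # planted module membership (module genes only)
    module_terms: dict[str, str]  # module id -> planted term id
    group_means: dict[str, float]  # biomarker mean per group (+ subtype split)
    hazard_ratio: float
    subtype: pd.Series | None = None  # per-sample GCB / non-GCB / unknown
    factor_values: pd.DataFrame | None = None

    def module_labels(self, genes) -> list[str]:
        return [self.module_of.get(g, "background") for g in genes]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    matrix: pd.DataFrame
    sheet: pd.DataFrame
    catalog: GeneCatalog
    truth: SyntheticTruth


def _sample_layout(config: SyntheticConfig):
    groups: list[str] = []
    for stage in STAGES:
        groups += [stage] * config.n_per_stage
    groups += [TUMOR_GROUP] * config.n_tumor
    ids = [f"S{i + 1:04d}" for i in range(len(groups))]
    return ids, np.array(groups)


def generate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GeneCatalog, SyntheticTruth]:
    """Simulate the log2 expression matrix, catalog and planted truth."""
    rng = np.random.default_rng(config.seed)
    coding = [f"PCG{i + 1:04d}" for i in range(config.n_coding)]
    lnc = [f"LNC{i + 1:04d}" for i in range(config.n_lnc)]
    genes = coding + lnc
    sample_ids, groups = _sample_layout(config)
    tumor = groups == TUMOR_GROUP
    n_samples = len(sample_ids)
    sigma = config.noise_sd

    # module memberships: consecutive blocks of coding and lncRNA genes
    module_of: dict[str, str] = {}
    for m in range(config.n_modules):
        mid = f"module_{m + 1}"
        c0 = m * config.coding_per_module
        l0 = m * config.lnc_per_module
        for g in coding[c0 : c0 + config.coding_per_module]:
            module_of[g] = mid
        for g in lnc[l0 : l0 + config.lnc_per_module]:
            module_of[g] = mid
    biomarker = lnc[0]  # first lncRNA of module_1
    trio = coding[: config.trio_size]  # coding partners inside module_1

    baseline = rng.normal(7.0, 1.0, len(genes))
    values = baseline[:, None] + rng.normal(0.0, sigma, (len(genes), n_samples))

    # subtype labels for tumor samples (fixed margin, randomised placement)
    n_gcb = int(round(config.gcb_fraction * config.n_tumor))
    subtype_tumor = np.array(["non-GCB"] * config.n_tumor)
    subtype_tumor[rng.permutation(config.n_tumor)[:n_gcb]] = "GCB"
    subtype = np.full(n_samples, "unknown", dtype=object)
    subtype[tumor] = subtype_tumor

    # latent module factors act in the tumor samples (where the network is built)
    lam = sigma * np.sqrt(config.module_rho / (1.0 - config.module_rho))
    gene_pos = {g: i for i, g in enumerate(genes)}
    factors = rng.normal(0.0, 1.0, (config.n_modules, config.n_tumor))
    skip = set(trio) | {biomarker}
    for m in range(config.n_modules):
        mid = f"module_{m + 1}"
        rows = [gene_pos[g] for g, mm in module_of.items() if mm == mid and g not in skip]
        values[np.ix_(rows, np.where(tumor)[0])] += lam * factors[m]

    # planted biomarker: reduced loading on its module factor, down-shifted in
    # tumor, lifted in GCB tumor samples
    b_row = gene_pos[biomarker]
    values[b_row, tumor] += config.biomarker_loading * factors[0]
    values[b_row, tumor] -= config.biomarker_delta
    values[b_row, (subtype == "GCB")] += config.subtype_delta

    # trio: coding partners sharing the biomarker's full deviation (tumor
    # down-shift, GCB lift, factor + noise) so the within-tumor correlation
    # hits trio_rho while staying correlated (~rho·λ_b/λ) with module members
    deviation = values[b_row] - baseline[b_row]
    p_gcb = config.gcb_fraction
    var_tumor = (
        config.biomarker_loading**2
        + sigma**2
        + config.subtype_delta**2 * p_gcb * (1.0 - p_gcb)
    )
    tau = np.sqrt(var_tumor) * np.sqrt(1.0 / config.trio_rho**2 - 1.0)
    for g in trio:
        row = gene_pos[g]
        values[row] = baseline[row] + deviation + rng.normal(0.0, tau, n_samples)

    mat = pd.DataFrame(values, index=genes, columns=sample_ids)
    catalog = GeneCatalog(
        biotype={**{g: "coding" for g in coding}, **{g: "lncRNA" for g in lnc}}
    )
    means = {stage: float(baseline[b_row]) for stage in STAGES}
    means["DLBCL:non-GCB"] = float(baseline[b_row] - config.biomarker_delta)
    means["DLBCL:GCB"] = float(
        baseline[b_row] - config.biomarker_delta + config.subtype_delta
    )
    truth = SyntheticTruth(
        biomarker=biomarker,
        trio=list(trio),
        module_of=module_of,
        module_terms={},
        group_means=means,
        hazard_ratio=config.hazard_ratio,
        subtype=pd.Series(subtype, index=sample_ids),
        factor_values=pd.DataFrame(
            factors.T,
            index=np.array(sample_ids)[tumor],
            columns=[f"module_{m + 1}" for m in range(config.n_modules)],
        ),
    )
    return mat, catalog, truth


def generate_survival(
    config: SyntheticConfig, biomarker_values: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential survival with hazard × HR in the low mean-split stratum.

    Censoring is an independent exponential whose rate is calibrated so the
    expected censored fraction matches the target.  Times in months.
    """
    split = mean_split(biomarker_values)
    low = (split.labels == "low").to_numpy()
    lam_high = np.log(2.0) / config.baseline_median_months
    rates = lam_high * np.where(low, config.hazard_ratio, 1.0)
    event_times = rng.exponential(1.0 / rates)
    if config.censoring_fraction > 0:
        frac_low = low.mean()

        def expected_censoring(c):
            return (
                frac_low * c / (c + lam_high * config.hazard_ratio)
                + (1 - frac_low) * c / (c + lam_high)
                - config.censoring_fraction
            )

        c_rate = brentq(expected_censoring, 1e-10, 1e3)
        censor_times = rng.exponential(1.0 / c_rate, len(event_times))
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time, event = event_times, np.ones(len(event_times), int)
    return pd.DataFrame(
        {"time": time, "event": event}, index=biomarker_values.index
    )


def generate_terms(
    config: SyntheticConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """One planted term per module (its coding members) plus random decoys."""
    coding_all = sorted(g for g in truth.module_of if g.startswith("PCG"))
    coding_universe = [f"PCG{i + 1:04d}" for i in range(config.n_coding)]
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for m in range(config.n_modules):
        mid = f"module_{m + 1}"
        term = f"TERM_M{m + 1}"
        terms[term] = {g for g in coding_all if truth.module_of[g] == mid}
        names[term] = f"planted program of {mid}"
        truth.module_terms[mid] = term
    for d in range(config.n_decoy_terms):
        term = f"TERM_D{d + 1:02d}"
        size = config.coding_per_module
        members = rng.choice(coding_universe, size=size, replace=False)
        terms[term] = set(members.tolist())
        names[term] = "decoy gene set"
    return terms, names


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full bundle: matrix, sample sheet, catalog with terms, planted truth."""
    mat, catalog, truth = generate_expression(config)
    subtype = truth.subtype.to_numpy()
    sample_ids, groups = _sample_layout(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tumor_mask = groups == TUMOR_GROUP
    tumor_ids = np.array(sample_ids)[tumor_mask]
    surv = generate_survival(config, mat.loc[truth.biomarker, tumor_ids], rng)

    sheet = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    sheet["subtype"] = subtype
    sheet = sheet.set_index("sample_id", drop=False)
    for col in ("time", "event", "age", "ipi"):
        sheet[col] = np.nan
    sheet["endpoint"] = "unknown"
    sheet["gender"] = "unknown"
    sheet.loc[surv.index, "time"] = surv["time"]
    sheet.loc[surv.index, "event"] = surv["event"]
    sheet.loc[surv.index, "endpoint"] = "OS"
    n_t = int(tumor_mask.sum())
    sheet.loc[tumor_ids, "gender"] = np.where(rng.random(n_t) < 96 / 170, "Male", "Female")
    sheet.loc[tumor_ids, "age"] = np.clip(np.round(rng.normal(62, 12, n_t)), 18, 95)
    sheet.loc[tumor_ids, "ipi"] = rng.choice(
        6, size=n_t, p=[0.12, 0.25, 0.30, 0.15, 0.12, 0.06]
    )
    terms, names = generate_terms(config, truth, rng)
    catalog.terms = terms
    catalog.term_names = names
    return SyntheticDataset(config=config, matrix=mat, sheet=sheet, catalog=catalog, truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the standard file formats plus truth/config echoes; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "expression.tsv",
        "sheet": outdir / "samples.tsv",
        "biotypes": outdir / "biotypes.tsv",
        "gmt": outdir / "terms.gmt",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    write_expression_matrix(dataset.matrix, paths["matrix"])
    write_sample_sheet(dataset.sheet, paths["sheet"])
    write_biotype_table(dataset.catalog.biotype, paths["biotypes"])
    write_gmt(dataset.catalog.terms, dataset.catalog.term_names, paths["gmt"])
    truth = dataset.truth
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "biomarker": truth.biomarker,
                "trio": truth.trio,
                "module_of": truth.module_of,
                "module_terms": truth.module_terms,
                "group_means": truth.group_means,
                "hazard_ratio": truth.hazard_ratio,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(dataset.config.to_dict(), fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
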