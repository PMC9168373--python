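"""Synthetic bulk-transcriptome cohorts with known immune composition.

Every downstream stage of the pipeline (deconvolution, subtype clustering,
stability selection, scoring, survival analysis, mutation comparison) is
validated against cohorts produced here, because each cohort carries its own
ground truth: the true cell fractions behind every bulk profile, the planted
infiltration subtype, the latent prognostic score that drives survival, and
the module membership of every informative gene.

The generative model
--------------------
* Each sample belongs to one of ``n_subtypes`` infiltration subtypes. Its
  cell-type fractions are drawn from a Dirichlet whose mean is the subtype's
  fraction profile and whose common concentration (default 50) sets the
  within-subtype variability the clustering must tolerate.
* Marker-gene expression is the signature-weighted mixture ``S @ F.T`` on the
  linear (TPM-like) scale; multiplicative log-normal noise preserves
  nonnegativity and vanishes exactly at ``noise_sd = 0``.
* Prognostic gene modules add score-linked offsets on the log2 scale before
  exponentiation, so module effect sizes read directly as log2 fold changes
  per unit of latent score.
* Overall survival is exponential with hazard proportional to
  ``exp(log_hr * latent score)``; independent exponential censoring is tuned
  by bisection to hit the requested censoring rate.
* Somatic mutations are Bernoulli per gene and sample, with rates that may
  differ between the high- and low-score halves of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth, SignatureMatrix, Unit

# Cell types mirroring the 22 leukocyte phenotypes of an LM22-style reference.
LM22_LIKE_CELL_TYPES = [
    "B_cells_naive", "B_cells_memory", "Plasma_cells",
    "T_cells_CD8", "T_cells_CD4_naive", "T_cells_CD4_memory_resting",
    "T_cells_CD4_memory_activated", "T_cells_follicular_helper",
    "T_cells_regulatory_Tregs", "T_cells_gamma_delta",
    "NK_cells_resting", "NK_cells_activated", "Monocytes",
    "Macrophages_M0", "Macrophages_M1", "Macrophages_M2",
    "Dendritic_cells_resting", "Dendritic_cells_activated",
    "Mast_cells_resting", "Mast_cells_activated",
    "Eosinophils", "Neutrophils",
]

# Cell types over-represented in each default subtype, echoing the four
# infiltration patterns the classifier is meant to separate: S1 mast/DC/Treg,
# S2 humoral (B/plasma/activated CD4), S3 suppressive macrophage-rich,
# S4 cytotoxic/immune-active.
_DEFAULT_SUBTYPE_BOOSTS = [
    ["Mast_cells_resting", "Dendritic_cells_activated",
     "T_cells_regulatory_Tregs", "Monocytes"],
    ["B_cells_naive", "Plasma_cells", "T_cells_CD4_memory_activated",
     "B_cells_memory"],
    ["Macrophages_M0", "Macrophages_M2", "T_cells_CD4_memory_resting",
     "Neutrophils"],
    ["T_cells_CD8", "NK_cells_resting", "T_cells_follicular_helper",
     "Macrophages_M1"],
]

_SIGNATURE_SEED = 20220  # fixed: the bundled reference is a constant artifact


@dataclass(frozen=True)
class ModuleSpec:
    """A planted prognostic gene module.

    ``direction`` is +1 for hazard-increasing modules (expression rises with
    the latent risk score) and -1 for hazard-decreasing ones; ``log2fc`` is
    the expression slope per unit of latent score on the log2 scale.
    """

    name: str
    n_genes: int
    direction: int
    log2fc: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("module direction must be +1 or -1")
        if self.n_genes < 1:
            raise ValueError("module needs at least one gene")


def default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec("risk", 30, +1, 1.0),
        ModuleSpec("protective", 20, -1, 1.0),
    ]


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort."""

    n_samples: int = 200
    n_genes: int = 1000
    n_cell_types: int = 22
    n_subtypes: int = 4
    subtype_fraction_profiles: np.ndarray | None = None  # subtypes x cell types
    dirichlet_concentration: float = 50.0
    modules: list[ModuleSpec] = field(default_factory=default_modules)
    noise_sd: float = 0.25          # log2-scale multiplicative noise
    missing_frac: float = 0.0
    n_batches: int = 1
    batch_shift_sd: float = 0.0     # log2-scale per-gene batch offsets
    log_hr: float = 1.0             # survival effect of the latent score
    baseline_rate: float = 1.0 / 1000.0   # events per day
    censoring_rate: float = 0.3
    subtype_score_spread: float = 1.0     # subtype means span +/- this value
    score_noise_sd: float = 0.3           # within-subtype prognostic frailty
    mutation_rates: dict[str, tuple[float, float]] | None = None  # gene -> (high, low)
    seed: int = 0

    def validate(self, signature: SignatureMatrix) -> None:
        if self.n_subtypes < 2:
            raise ValueError("need at least 2 subtypes")
        if not 0.0 <= self.missing_frac < 0.7:
            raise ValueError("missing_frac must lie in [0, 0.7) so that "
                             "informative genes survive the 70% filter")
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if signature.values.shape[1] != self.n_cell_types:
            raise ValueError(
                f"signature has {signature.values.shape[1]} cell types, "
                f"config expects {self.n_cell_types}")
        profiles = self.profiles()
        if profiles.shape != (self.n_subtypes, self.n_cell_types):
            raise ValueError("subtype_fraction_profiles shape mismatch")
        if not np.allclose(profiles.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each subtype fraction profile must sum to 1")
        n_module = sum(m.n_genes for m in self.modules)
        if signature.values.shape[0] + n_module > self.n_genes:
            raise ValueError("n_genes too small for signature plus modules")

    def profiles(self) -> np.ndarray:
        if self.subtype_fraction_profiles is not None:
            return np.asarray(self.subtype_fraction_profiles, dtype=float)
        return default_subtype_profiles(self.n_subtypes, self.n_cell_types)


def default_subtype_profiles(n_subtypes: int = 4,
                             n_cell_types: int = 22,
                             boost: float = 7.0) -> np.ndarray:
    """Dirichlet mean fraction profiles for the planted subtypes.

    Each subtype over-represents four cell types by ``boost`` relative to the
    rest. For the default 4 x 22 case the boosted types follow the canonical
    infiltration patterns; other shapes cycle boosts positionally.
    """
    profiles = np.ones((n_subtypes, n_cell_types))
    if n_subtypes == 4 and n_cell_types == 22:
        for s, names in enumerate(_DEFAULT_SUBTYPE_BOOSTS):
            for name in names:
                profiles[s, LM22_LIKE_CELL_TYPES.index(name)] = boost
    else:
        per = max(1, n_cell_types // n_subtypes)
        for s in range(n_subtypes):
            for j in range(per):
                profiles[s, (s * per + j) % n_cell_types] = boost
    return profiles / profiles.sum(axis=1, keepdims=True)


def bundled_signature(n_markers_per_type: int = 20,
                      n_cell_types: int = 22,
                      marker_log2_mean: float = 9.0,
                      background_log2_mean: float = 4.0,
                      log2_sd: float = 0.5) -> SignatureMatrix:
    """Deterministic block-structured reference signature.

    Each cell type gets ``n_markers_per_type`` marker genes expressed ~32x
    above background in that type; a drop-in stand-in for an LM22-style
    reference, replaceable by any genes x cell-types TSV.
    """
    rng = np.random.default_rng(_SIGNATURE_SEED)
    n_genes = n_markers_per_type * n_cell_types
    log2 = rng.normal(background_log2_mean, log2_sd, size=(n_genes, n_cell_types))
    for c in range(n_cell_types):
        rows = slice(c * n_markers_per_type, (c + 1) * n_markers_per_type)
        log2[rows, c] = rng.normal(marker_log2_mean, log2_sd, n_markers_per_type)
    cell_types = (LM22_LIKE_CELL_TYPES if n_cell_types == 22
                  else [f"cell_type_{c+1:02d}" for c in range(n_cell_types)])
    genes = [f"SIG{g+1:04d}" for g in range(n_genes)]
    values = pd.DataFrame(np.exp2(log2), index=genes, columns=cell_types)
    return SignatureMatrix(values)


def default_mutation_rates(n_genes: int = 25, n_differential: int = 6,
                           rate_high: float = 0.45, rate_low: float = 0.15,
                           rate_base: float = 0.20) -> dict[str, tuple[float, float]]:
    """Per-gene mutation probabilities for the (high, low) score groups."""
    rates: dict[str, tuple[float, float]] = {}
    for g in range(n_genes):
        name = f"MUTG{g+1:02d}"
        if g < n_differential:
            rates[name] = (rate_high, rate_low)
        else:
            rates[name] = (rate_base, rate_base)
    return rates


def _censoring_rate_for(c: float, hazards: np.ndarray) -> float:
    # P(censor before event) for exponential race with censoring rate c
    return float(np.mean(c / (c + hazards)))


def _solve_censoring_rate(target: float, hazards: np.ndarray) -> float:
    """Bisection for the censoring rate hitting the target censored fraction."""
    if target <= 0:
        return 0.0
    if target >= 1:
        raise ValueError("censoring_rate must be < 1")
    lo, hi = 0.0, float(hazards.max())
    while _censoring_rate_for(hi, hazards) < target:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _censoring_rate_for(mid, hazards) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(latent_score: pd.Series | np.ndarray,
                      log_hr: float,
                      baseline_rate: float,
                      censoring_rate: float,
                      seed: int) -> pd.DataFrame:
    """Exponential survival with hazard ``baseline_rate * exp(log_hr*score)``.

    Censoring is an independent exponential clock whose rate is solved by
    bisection so the expected censored fraction equals ``censoring_rate``.
    Returns a DataFrame with ``time`` (days) and ``event`` (1 = death).
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must lie in [0, 1)")
    score = np.asarray(latent_score, dtype=float)
    index = (latent_score.index if isinstance(latent_score, pd.Series)
             else pd.RangeIndex(len(score)))
    rng = np.random.default_rng(seed)
    hazards = baseline_rate * np.exp(log_hr * score)
    event_time = rng.exponential(1.0 / hazards)
    c = _solve_censoring_rate(censoring_rate, hazards)
    if c > 0:
        censor_time = rng.exponential(1.0 / c, size=len(score))
    else:
        censor_time = np.full(len(score), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-8)  # survival times must stay positive
    return pd.DataFrame({"time": time, "event": event}, index=index)


def simulate_cohort(config: SimConfig,
                    signature: SignatureMatrix | None = None,
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a full synthetic cohort.

    Returns (expression TPM, clinical table, MAF table, ground truth). The
    same config and seed always yield bit-identical outputs.
    """
    if signature is None:
        signature = bundled_signature(n_cell_types=config.n_cell_types)
    config.validate(signature)
    root = np.random.SeedSequence(config.seed)
    (ss_subtype, ss_frac, ss_score, ss_expr, ss_batch, ss_miss, ss_surv,
     ss_clin, ss_maf) = root.spawn(9)

    n, p = config.n_samples, config.n_genes
    samples = [f"SAMPLE_{i+1:04d}" for i in range(n)]
    sig_genes = list(signature.gene_ids)
    profiles = config.profiles()

    # --- subtypes and cell fractions -------------------------------------
    rng = np.random.default_rng(ss_subtype)
    subtype = rng.integers(0, config.n_subtypes, size=n) + 1
    rng = np.random.default_rng(ss_frac)
    fractions = np.empty((n, config.n_cell_types))
    for i in range(n):
        alpha = config.dirichlet_concentration * profiles[subtype[i] - 1]
        fractions[i] = rng.dirichlet(alpha)

    # --- latent prognostic score -----------------------------------------
    rng = np.random.default_rng(ss_score)
    if config.n_subtypes > 1:
        means = np.linspace(-config.subtype_score_spread,
                            config.subtype_score_spread, config.n_subtypes)
    else:
        means = np.zeros(1)
    score = means[subtype - 1] + rng.normal(0.0, config.score_noise_sd, n)

    # --- expression --------------------------------------------------------
    rng = np.random.default_rng(ss_expr)
    sig_block = signature.values.to_numpy() @ fractions.T  # genes x samples
    module_membership: dict[str, str] = {}
    blocks = [sig_block]
    gene_ids = list(sig_genes)
    for m in config.modules:
        base = rng.uniform(4.0, 8.0, size=m.n_genes)
        log2 = base[:, None] + m.direction * m.log2fc * score[None, :]
        blocks.append(np.exp2(log2))
        names = [f"{m.name.upper()}{g+1:03d}" for g in range(m.n_genes)]
        gene_ids.extend(names)
        module_membership.update({g: m.name for g in names})
    n_filler = p - len(gene_ids)
    if n_filler > 0:
        base = rng.uniform(2.0, 8.0, size=n_filler)
        blocks.append(np.exp2(np.broadcast_to(base[:, None], (n_filler, n)).copy()))
        gene_ids.extend(f"NOISE{g+1:04d}" for g in range(n_filler))
    expr = np.vstack(blocks)
    if config.noise_sd > 0:
        expr = expr * np.exp2(rng.normal(0.0, config.noise_sd, size=expr.shape))

    # --- batch structure ----------------------------------------------------
    rng = np.random.default_rng(ss_batch)
    batch = rng.integers(0, config.n_batches, size=n) + 1
    if config.n_batches > 1 and config.batch_shift_sd > 0:
        shifts = rng.normal(0.0, config.batch_shift_sd,
                            size=(p, config.n_batches))
        expr = expr * np.exp2(shifts[:, batch - 1])

    # TPM scaling: every library sums to 1e6
    expr = expr / expr.sum(axis=0, keepdims=True) * 1e6
    values = pd.DataFrame(expr, index=gene_ids, columns=samples)

    mask = None
    if config.missing_frac > 0:
        rng = np.random.default_rng(ss_miss)
        mask = pd.DataFrame(rng.random(size=expr.shape) < config.missing_frac,
                            index=gene_ids, columns=samples)
    expression = ExpressionMatrix(values, Unit.TPM, mask)

    # --- survival and clinical covariates ----------------------------------
    score_s = pd.Series(score, index=samples, name="latent_score")
    surv = simulate_survival(score_s, config.log_hr, config.baseline_rate,
                             config.censoring_rate,
                             int(ss_surv.generate_state(1)[0] % (2**31)))
    rng = np.random.default_rng(ss_clin)
    clinical = pd.DataFrame({
        "os_days": surv["time"].to_numpy(),
        "os_event": surv["event"].to_numpy(),
        "age": rng.normal(65.0, 9.0, n).round(1),
        "sex": rng.choice(["F", "M"], n),
        "stage": rng.choice(["I", "II", "III", "IV"], n,
                            p=[0.5, 0.25, 0.18, 0.07]),
        "smoke": rng.choice([0, 1], n, p=[0.2, 0.8]),
        "batch": batch,
    }, index=pd.Index(samples, name="sample"))

    # --- somatic mutations ---------------------------------------------------
    rates = (config.mutation_rates if config.mutation_rates is not None
             else default_mutation_rates())
    rng = np.random.default_rng(ss_maf)
    high = score >= np.median(score)
    classes = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
               "Frame_Shift_Ins", "Splice_Site", "Silent"]
    class_p = [0.55, 0.12, 0.10, 0.06, 0.07, 0.10]
    rows = []
    for gene, (r_high, r_low) in rates.items():
        prob = np.where(high, r_high, r_low)
        mutated = rng.random(n) < prob
        for i in np.flatnonzero(mutated):
            vc = classes[rng.choice(len(classes), p=class_p)]
            vt = "DEL" if vc == "Frame_Shift_Del" else (
                "INS" if vc == "Frame_Shift_Ins" else "SNP")
            rows.append((gene, samples[i], vc, vt))
    maf = pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                                      "Variant_Classification", "Variant_Type"])

    truth = GroundTruth(
        true_fractions=pd.DataFrame(fractions, index=samples,
                                    columns=signature.cell_type_ids),
        true_subtype=pd.Series(subtype, index=samples, name="subtype"),
        true_latent_score=score_s,
        module_membership=module_membership,
        batch=pd.Series(batch, index=samples, name="batch"),
    )
    return expression, clinical, maf, truth


def write_cohort(outdir, expression: ExpressionMatrix, clinical: pd.DataFrame,
                 maf: pd.DataFrame, truth: GroundTruth) -> None:
    """Persist a simulated cohort as plain TSV/MAF files."""
    from pathlib import Path

    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_expression(expression, outdir / "expression.tsv")
    tio.write_clinical(clinical, outdir / "clinical.tsv")
    tio.write_maf(maf, outdir / "mutations.maf")
    truth.true_fractions.to_csv(outdir / "truth_fractions.tsv", sep="\t",
                                index_label="sample")
    pd.DataFrame({
        "subtype": truth.true_subtype,
        "latent_score": truth.true_latent_score,
        "batch": truth.batch,
    }).to_csv(outdir / "truth_samples.tsv", sep="\t", index_label="sample")
    pd.Series(truth.module_membership, name="module").to_csv(
        outdir / "truth_modules.tsv", sep="\t", index_label="gene")
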