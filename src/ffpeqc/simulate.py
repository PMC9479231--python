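"""Synthetic FFPE RNA-seq cohorts.

Formalin fixation fragments RNA; in exome-capture RNA-seq of archival
tissue this shows up as (a) loss of signal that is worst for short and
GC-rich genes, (b) inflated replicate-to-replicate variability in
degraded samples, and (c) pre-sequencing lab measurements (RNA and
pre-capture library concentration, DV fragment-size percentages) that
track a sample's latent quality. The generators here emulate exactly
that structure so every downstream stage — normalization, QC metrics,
replicate statistics, threshold derivation and the QC predictor — can
be exercised end to end without real data.

Counts follow a negative binomial (gamma-Poisson) model. For a sample
of latent quality ``q`` in [0, 1], the expected count of gene ``g`` is

    mu_g = depth * p_g * bio_g * exp(-dropout_strength * (1 - q) * w_g)

where ``p_g`` is proportional to base expression times exonic length,
``bio_g`` a specimen-level biological factor shared by replicates, and
``w_g`` a normalized degradation weight increasing with GC fraction
and decreasing with log length. Degraded samples additionally receive
multiplicative log-normal noise with standard deviation proportional
to ``(1 - q) * w_g``, which is what drives the MAD-vs-length and
MAD-vs-GC structure and the higher replicate FPR of poor samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

RNA_RULE_CUTOFF = 25.0  # ng/ul, minimum RNA concentration in the planted rule
LIB_RULE_CUTOFF = 1.7  # ng/ul, minimum pre-capture library concentration


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic cohort.

    All defaults are implementer choices (no generative parameters are
    published for the emulated study design); see docs/methods.md for
    the rationale behind each value.
    """

    n_genes: int = 2000
    n_samples: int = 60
    n_batches: int = 5
    n_replicate_groups: int = 4
    dispersion: float = 0.02
    dropout_strength: float = 2.0
    length_effect: float = 1.0
    gc_effect: float = 1.0
    labmetric_noise_sd: float = 3.0
    label_noise: float = 0.05
    seed: int = 0
    mean_depth: float = 2.5e6
    degradation_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_batches", "n_replicate_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.dropout_strength < 0 or self.degradation_noise_sd < 0:
            raise ValueError("degradation strengths must be non-negative")


def generate_gene_catalog(n_genes: int, seed: int) -> pd.DataFrame:
    """Gene catalog: exonic length (bp), GC fraction and base expression.

    Lengths are log-normal (heavy tailed) clipped to [200, 100000] bp;
    GC fractions Beta-distributed over [0.3, 0.7]; base expression
    log-normal across ~3 orders of magnitude. Deterministic per seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    length = np.clip(np.exp(rng.normal(np.log(1500.0), 1.0, n_genes)), 200, 100_000)
    gc = 0.3 + 0.4 * rng.beta(5.0, 5.0, n_genes)
    base = np.exp(rng.normal(np.log(10.0), 1.5, n_genes))
    return pd.DataFrame(
        {
            "length_bp": np.round(length).astype(int),
            "gc_frac": gc,
            "base_mean": base,
        },
        index=pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id"),
    )


def generate_cohort_truth(params: SimulationParams) -> pd.DataFrame:
    """Cohort design: latent quality, batches, controls, replicates.

    Study samples get latent quality ~ U(0.15, 0.95) and are batched by
    quality (mirroring the practice of sequencing similar-quality
    samples together); every batch carries one FFPE technical-control
    replicate (fixed good quality, shared replicate group across
    batches) and the first ``n_replicate_groups`` study samples are
    duplicated into a neighboring batch as study replicates.
    ``true_status`` is PASS for quality >= 0.45.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    quality = np.sort(rng.uniform(0.15, 0.95, n))[::-1]
    batch = np.array_split(np.arange(n), params.n_batches)
    # one control specimen re-sequenced in every batch -> one latent quality
    ctrl_quality = float(np.clip(0.8 + 0.02 * rng.standard_normal(), 0, 1))
    rows = []
    for b, members in enumerate(batch):
        bid = f"batch{b + 1}"
        rows.append(
            {
                "sample_id": f"CTRL_b{b + 1}",
                "quality": ctrl_quality,
                "batch_id": bid,
                "replicate_group": "ctrl_ffpe",
                "is_technical_control": True,
            }
        )
        for i in members:
            rows.append(
                {
                    "sample_id": f"S{i + 1:03d}",
                    "quality": float(quality[i]),
                    "batch_id": bid,
                    "replicate_group": None,
                    "is_technical_control": False,
                }
            )
    n_rep = min(params.n_replicate_groups, n)
    df = pd.DataFrame(rows).set_index("sample_id")
    study = df.index[~df["is_technical_control"]]
    batches = [f"batch{b + 1}" for b in range(params.n_batches)]
    for r in range(n_rep):
        sid = study[r]
        group = f"rep{r + 1}"
        df.loc[sid, "replicate_group"] = group
        other = batches[(batches.index(df.loc[sid, "batch_id"]) + 1) % len(batches)]
        df.loc[f"{sid}_rep"] = {
            "quality": df.loc[sid, "quality"],
            "batch_id": other,
            "replicate_group": group,
            "is_technical_control": False,
        }
    df["true_status"] = np.where(df["quality"] >= 0.45, "PASS", "FAIL")
    return df


def _degradation_weights(catalog: pd.DataFrame, length_effect: float, gc_effect: float) -> np.ndarray:
    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    raw = gc_effect * z(catalog["gc_frac"]) - length_effect * z(np.log(catalog["length_bp"]))
    if np.ptp(raw) == 0:
        return np.ones(len(catalog))
    w = (raw - raw.min()) / np.ptp(raw)  # min-max to [0, 1]
    return 2.0 * w  # mean ~1 so dropout_strength keeps its scale


def simulate_counts(
    catalog: pd.DataFrame,
    truth: pd.DataFrame,
    params: SimulationParams,
) -> ExpressionMatrix:
    """Negative-binomial counts with quality-dependent degradation.

    Samples sharing a ``replicate_group`` share the specimen-level
    biological expression profile but receive independent degradation
    noise and counting noise. Deterministic per ``params.seed``.
    """
    if len(catalog) == 0 or len(truth) == 0:
        raise ValueError("catalog and cohort must be non-empty")
    rng = np.random.default_rng(params.seed + 1)
    n_genes = len(catalog)
    rel = (catalog["base_mean"] * catalog["length_bp"]).to_numpy(dtype=float)
    p_g = rel / rel.sum()
    w = _degradation_weights(catalog, params.length_effect, params.gc_effect)
    # one biological profile per specimen (replicate group or singleton sample)
    bio: dict[str, np.ndarray] = {}
    cols = {}
    shape = 1.0 / params.dispersion
    for sid, row in truth.iterrows():
        group = row["replicate_group"]
        key = str(group) if group not in (None, np.nan) and not pd.isna(group) else f"__{sid}"
        if key not in bio:
            bio[key] = np.exp(rng.normal(0.0, 0.5, n_genes))
        q = float(row["quality"])
        mu = params.mean_depth * p_g * bio[key]
        mu = mu * np.exp(-params.dropout_strength * (1.0 - q) * w)
        sd = params.degradation_noise_sd * (1.0 - q) * w
        if sd.max() > 0:
            mu = mu * np.exp(rng.normal(0.0, 1.0, n_genes) * sd - 0.5 * sd**2)
        lam = rng.gamma(shape, mu / shape)
        cols[sid] = rng.poisson(lam)
    values = pd.DataFrame(cols, index=catalog.index)
    if list(values.columns) != list(truth.index):
        raise ValueError("sample dimension mismatch between truth and generated counts")
    return ExpressionMatrix(values, "counts")


def simulate_lab_metrics(
    truth: pd.DataFrame,
    params: SimulationParams,
    planted_rule: bool = False,
) -> pd.DataFrame:
    """Pre-sequencing lab metrics linked to latent quality.

    RNA and library concentrations are noisy increasing functions of
    quality (calibrated so the 25 / 1.7 ng/ul decision thresholds fall
    mid-range); DV50/100/200 are logistic in quality. With
    ``planted_rule=True`` the returned ``true_status`` is recomputed
    from the concentration rule (PASS iff rna >= 25 and lib >= 1.7) and
    then flipped independently with probability ``label_noise``.
    """
    if len(truth) == 0:
        raise ValueError("cohort must be non-empty")
    rng = np.random.default_rng(params.seed + 2)
    q = truth["quality"].to_numpy(dtype=float)
    n = q.size
    rna = np.clip(5.0 + 55.0 * q + rng.normal(0, params.labmetric_noise_sd, n), 0.0, None)
    lib = np.clip(
        0.2 + 7.8 * q + rng.normal(0, params.labmetric_noise_sd / 10.0, n), 0.0, None
    )
    dv200 = np.clip(100 / (1 + np.exp(-6 * (q - 0.25))) + rng.normal(0, 3, n), 0, 100)
    dv100 = np.clip(100 / (1 + np.exp(-6 * (q - 0.45))) + rng.normal(0, 3, n), 0, 100)
    dv50 = np.clip(100 / (1 + np.exp(-6 * (q - 0.6))) + rng.normal(0, 3, n), 0, 100)
    out = pd.DataFrame(
        {
            "rna_qubit": rna,
            "library_qubit": lib,
            "dv50": dv50,
            "dv100": dv100,
            "dv200": dv200,
            "batch_id": truth["batch_id"],
            "replicate_group": truth["replicate_group"],
            "is_technical_control": truth["is_technical_control"],
            "true_status": truth["true_status"],
        },
        index=truth.index,
    )
    if planted_rule:
        out["true_status"] = apply_planted_rule(
            out["rna_qubit"], out["library_qubit"], params.label_noise, rng
        )
    return out


def apply_planted_rule(rna_qubit, library_qubit, label_noise: float, rng) -> np.ndarray:
    """PASS iff rna >= 25 ng/ul and library >= 1.7 ng/ul, then each
    label flipped independently with probability ``label_noise``."""
    rna = np.asarray(rna_qubit, dtype=float)
    lib = np.asarray(library_qubit, dtype=float)
    status = (rna >= RNA_RULE_CUTOFF) & (lib >= LIB_RULE_CUTOFF)
    flip = rng.random(rna.size) < label_noise
    return np.where(status ^ flip, "PASS", "FAIL")


def planted_rule_cohort(
    n_samples: int = 200, seed: int = 0, label_noise: float = 0.05
) -> pd.DataFrame:
    """Feature-independent cohort for predictor benchmarking.

    rna_qubit ~ U(5, 60), library_qubit ~ U(0.2, 8) (independent, so
    both decision thresholds are identifiable), labels from the planted
    concentration rule with the given flip probability.
    """
    rng = np.random.default_rng(seed)
    rna = rng.uniform(5.0, 60.0, n_samples)
    lib = rng.uniform(0.2, 8.0, n_samples)
    status = apply_planted_rule(rna, lib, label_noise, rng)
    return pd.DataFrame(
        {"rna_qubit": rna, "library_qubit": lib, "status": status},
        index=pd.Index([f"S{i + 1:03d}" for i in range(n_samples)], name="sample_id"),
    )


def simulate_cohort(params: SimulationParams) -> dict:
    """Full cohort bundle: catalog, truth, counts and lab metrics."""
    catalog = generate_gene_catalog(params.n_genes, params.seed)
    truth = generate_cohort_truth(params)
    counts = simulate_counts(catalog, truth, params)
    lab = simulate_lab_metrics(truth, params)
    return {"catalog": catalog, "truth": truth, "counts": counts, "lab_metrics": lab}


# ---------------------------------------------------------------------------
# Planted structures for threshold-derivation benchmarks


def planted_fpr_knee(
    n: int = 250,
    knee: float = 0.75,
    plateau: float = 0.20,
    slope: float = 0.8,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate FPR vs median correlation with a knee.

    Below the knee the FPR plateaus (detectable genes vanish in badly
    degraded samples, capping the apparent FPR); above it the FPR falls
    off linearly. The hinge at ``knee`` is the curvature maximum a
    knee-finder should recover.
    """
    rng = np.random.default_rng(seed)
    cor = rng.uniform(0.55, 0.95, n)
    fpr = np.where(cor < knee, plateau, plateau - slope * (cor - knee))
    fpr = np.clip(fpr + rng.normal(0, noise_sd, n), 0, 1)
    return cor, fpr


def planted_cor_tpm4(
    n: int = 120,
    tpm4_at_cutoff: float = 11_400.0,
    cor_at_cutoff: float = 0.75,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone correlation vs detected-genes relation crossing the
    planted point ``(cor_at_cutoff, tpm4_at_cutoff)``.

    gene_tpm4 ~ U(6000, 14000); the correlation is a sigmoid of the
    detected-gene count, centered so that the curve passes through the
    planted crossing, plus Gaussian noise. Returns ``(cor, tpm4)``.
    """
    rng = np.random.default_rng(seed)
    tpm4 = rng.uniform(6000.0, 14000.0, n)
    lo, amp, scale = cor_at_cutoff - 0.2, 0.4, 1500.0
    cor = lo + amp / (1 + np.exp(-(tpm4 - tpm4_at_cutoff) / scale))
    cor = cor + rng.normal(0, noise_sd, n)
    return cor, tpm4


def planted_saturation(
    n: int = 150,
    plateau: float = 13_000.0,
    fraction: float = 0.85,
    reads_at_fraction: float = 25e6,
    noise_sd: float = 200.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Detected genes vs gene reads following an exponential saturation
    curve whose ``fraction``-of-plateau point sits at
    ``reads_at_fraction``. Returns ``(reads, tpm4)``."""
    rng = np.random.default_rng(seed)
    tau = reads_at_fraction / -np.log(1 - fraction)
    reads = rng.uniform(2e6, 60e6, n)
    tpm4 = plateau * (1 - np.exp(-reads / tau)) + rng.normal(0, noise_sd, n)
    return reads, tpm4


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    """Copy of params with a different seed."""
    return replace(params, seed=seed)
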