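"""Sample- and line-level phenotype statistics.

Per sample (pot), each trait is summarised by its mean, a set of
percentiles (linear interpolation between order statistics) and the
relative standard deviation (RSD = sd / mean, with the n-1 sample sd).
Percentile phenotypes such as P95 capture the near-maximal fruit a plant
produced; RSD captures within-sample uniformity.

Line-level utilities cover the treatment contrast (a paired t-test on
per-genotype means), a broad-sense heritability estimate from one-way
ANOVA variance components, genotype-level exclusion bookkeeping, and a
mapping-ready phenotype/covariate export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

DEFAULT_PERCENTILES = (5, 25, 50, 75, 95)

TRAIT_VALUE_COLUMNS = ("SA_mm2", "SL_mm", "SD_mm", "SV_mm3")


def rsd(values) -> float:
    """Relative standard deviation: sample sd (n-1) over mean.

    Scale-invariant under positive rescaling.  Undefined for mean 0.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ValidationError("RSD undefined: mean is zero")
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    return float(sd / mean)


@dataclass
class SampleAggregate:
    """Per-sample summary of one trait plus QC bookkeeping."""

    sample_id: str
    trait: str
    mean: float
    percentiles: dict
    rsd: float
    n_accepted: int
    n_rejected: int

    @property
    def rejection_rate(self) -> float:
        total = self.n_accepted + self.n_rejected
        return self.n_rejected / total if total else float("nan")


def aggregate_sample(
    values,
    sample_id: str = "",
    trait: str = "",
    percentiles=DEFAULT_PERCENTILES,
    n_rejected: int = 0,
) -> SampleAggregate:
    """Summarise the accepted trait values of one sample.

    Raises :class:`ValidationError` with no accepted values — a sample
    with nothing measurable is *missing*, never zero.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError(f"sample {sample_id}: no accepted instances to aggregate")
    pct = {
        int(p): float(np.percentile(values, p, method="linear")) for p in percentiles
    }
    return SampleAggregate(
        sample_id=sample_id,
        trait=trait,
        mean=float(values.mean()),
        percentiles=pct,
        rsd=rsd(values),
        n_accepted=int(values.size),
        n_rejected=int(n_rejected),
    )


def aggregate_table(
    traits_df: pd.DataFrame,
    percentiles=DEFAULT_PERCENTILES,
    trait_columns=TRAIT_VALUE_COLUMNS,
) -> pd.DataFrame:
    """Tidy per-sample aggregate table from an instance-level trait table.

    Expects the trait-table schema (sample_id, qc_status, one column per
    trait).  Samples whose every instance failed QC are omitted (missing,
    not zero).  Returns one row per (sample_id, trait) with columns mean,
    p<q> for each percentile, rsd, n_accepted, n_rejected.
    """
    rows = []
    for sample_id, group in traits_df.groupby("sample_id", sort=True):
        accepted = group[group["qc_status"] == "accepted"]
        n_rej = int((group["qc_status"] == "rejected").sum())
        if accepted.empty:
            continue
        for col in trait_columns:
            agg = aggregate_sample(
                accepted[col].to_numpy(),
                sample_id=str(sample_id),
                trait=col,
                percentiles=percentiles,
                n_rejected=n_rej,
            )
            row = {
                "sample_id": agg.sample_id,
                "trait": agg.trait,
                "mean": agg.mean,
                **{f"p{p}": v for p, v in agg.percentiles.items()},
                "rsd": agg.rsd,
                "n_accepted": agg.n_accepted,
                "n_rejected": agg.n_rejected,
                "rejection_rate": agg.rejection_rate,
            }
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exclusion bookkeeping
# ---------------------------------------------------------------------------

def exclude_flagged(samples: pd.DataFrame, flagged_genotypes) -> tuple[pd.DataFrame, int]:
    """Drop every sample of each flagged genotype, across all batches and
    treatments; returns (kept, removed_count).

    Flags are applied at the genotype level: one aberrant plant removes
    all replicate samples of that line.  Flags naming unknown genotypes
    produce a warning.
    """
    flagged = set(flagged_genotypes)
    present = set(samples["genotype"])
    unknown = flagged - present
    if unknown:
        warnings.warn(f"exclusion flags for unknown genotypes: {sorted(unknown)}", stacklevel=2)
    drop = samples["genotype"].isin(flagged)
    kept = samples[~drop].reset_index(drop=True)
    return kept, int(drop.sum())


# ---------------------------------------------------------------------------
# treatment contrast
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    n_pairs: int
    n_dropped: int = 0
    degenerate: bool = False


def paired_treatment_test(
    line_values: pd.DataFrame,
    value_col: str = "value",
    line_col: str = "line",
    treatment_col: str = "treatment",
) -> PairedTestResult:
    """Paired t-test of the treatment contrast across genotypes.

    Each genotype contributes one pair: its mean value in each treatment
    (replicates averaged).  Genotypes observed in only one treatment are
    dropped and counted.  Identically zero differences are degenerate and
    flagged rather than tested.
    """
    means = (
        line_values.groupby([line_col, treatment_col])[value_col].mean().unstack(treatment_col)
    )
    if means.shape[1] != 2:
        raise ValidationError("paired test requires exactly two treatment levels")
    complete = means.dropna()
    n_dropped = len(means) - len(complete)
    if len(complete) < 2:
        raise ValidationError("paired test requires >= 2 genotypes in both treatments")
    a, b = complete.columns  # alphabetical: e.g. "group" - "isolation"
    diffs = (complete[a] - complete[b]).to_numpy()
    if np.allclose(diffs, 0):
        return PairedTestResult(
            t=0.0, df=len(diffs) - 1, p=1.0, n_pairs=len(diffs),
            n_dropped=n_dropped, degenerate=True,
        )
    t, p = stats.ttest_rel(complete[a], complete[b])
    return PairedTestResult(
        t=float(t), df=len(diffs) - 1, p=float(p), n_pairs=len(diffs), n_dropped=n_dropped
    )


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

def heritability_estimate(
    line_values: pd.DataFrame,
    value_col: str = "value",
    line_col: str = "line",
) -> float:
    """Broad-sense repeatability H^2 from one-way ANOVA components.

    H^2 = sigma2_line / (sigma2_line + sigma2_resid) with the variance
    components estimated by the method of moments: sigma2_resid = MSW,
    sigma2_line = (MSB - MSW) / n0, where n0 is the standard unbalanced
    correction n0 = (N - sum(n_i^2)/N) / (k - 1).  Clipped to [0, 1].

    Call with the samples of a single treatment; mixing treatments
    inflates the residual with the treatment contrast.
    """
    groups = line_values.groupby(line_col)[value_col]
    k = groups.ngroups
    if k < 2:
        raise ValidationError("heritability requires >= 2 lines")
    sizes = groups.size().to_numpy(dtype=float)
    if (sizes < 2).all():
        raise ValidationError("heritability requires replication within lines")
    n_total = sizes.sum()
    grand = line_values[value_col].mean()
    means = groups.mean().to_numpy()
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(((line_values[value_col] - groups.transform("mean")) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    n0 = (n_total - np.sum(sizes**2) / n_total) / (k - 1)
    sigma2_line = max((msb - msw) / n0, 0.0)
    total = sigma2_line + msw
    if total == 0:
        return 0.0
    return float(np.clip(sigma2_line / total, 0.0, 1.0))


# ---------------------------------------------------------------------------
# mapping-ready export
# ---------------------------------------------------------------------------

def export_qtl_tables(
    sample_aggregates: pd.DataFrame,
    manifest: pd.DataFrame,
    pheno_path,
    covar_path,
    metric: str = "p95",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write the two-file mapping-ready layout.

    ``pheno``: one row per sample, one column per trait for the chosen
    metric (default P95, the aggregate with the strongest line signal).
    ``covar``: sample -> genotype line, treatment, batch.  Both are keyed
    by sample_id so external mapping software can join them.
    """
    wide = sample_aggregates.pivot(index="sample_id", columns="trait", values=metric)
    wide.columns = [f"{c}_{metric}" for c in wide.columns]
    pheno = wide.reset_index()
    covar = manifest[["sample_id", "genotype", "treatment", "batch"]].copy()
    covar = covar[covar["sample_id"].isin(pheno["sample_id"])].reset_index(drop=True)
    pheno.to_csv(pheno_path, index=False, float_format="%.6f")
    covar.to_csv(covar_path, index=False)
    return pheno, covar
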