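"""SNP dosages, Hardy-Weinberg distributions, and polygenic scores.

Genotypes are handled as allele-2 dosages in [0, 2] (fractional values from
imputation are allowed).  The composite (unweighted) score sums the
allele-2 dosages of the three circadian SNPs — CLOCK rs1801260, PER3
rs2087947 and RASD1 rs11545787 — giving an integer-supported score 0..6 for
hard-called genotypes.  These SNPs sit on chromosomes 4, 1 and 17, so under
Hardy-Weinberg equilibrium the score distribution is an exact convolution
of independent per-SNP genotype distributions; no linkage disequilibrium is
modelled.  Allele-2 orientation is taken from the SNP definitions as given
and never silently flipped to minor-allele orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .study import SnpDef, COMPOSITE_SNPS

__all__ = [
    "hwe_genotype_probs",
    "composite_score_distribution",
    "all_heterozygote_probability",
    "unweighted_prs",
    "weighted_prs",
    "read_snp_table",
    "read_dosage_matrix",
    "read_vcf_dosages",
]


def hwe_genotype_probs(allele2_freq: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2)."""
    q = float(allele2_freq)
    if not (0.0 < q < 1.0):
        raise ValueError("allele2_freq must lie strictly in (0, 1)")
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


def composite_score_distribution(snps: list[SnpDef] | tuple[SnpDef, ...] = COMPOSITE_SNPS) -> np.ndarray:
    """Distribution of the unweighted composite score over 0..2k.

    Convolution of the per-SNP HWE genotype distributions, assuming
    independent (unlinked) SNPs.  Index i of the returned array is
    P(score = i); the probabilities sum to 1 to machine precision.
    """
    if len(snps) == 0:
        raise ValueError("need at least one SNP")
    dist = np.array([1.0])
    for snp in snps:
        dist = np.convolve(dist, np.asarray(hwe_genotype_probs(snp.allele2_freq)))
    return dist


def all_heterozygote_probability(snps: list[SnpDef] | tuple[SnpDef, ...] = COMPOSITE_SNPS) -> float:
    """Probability of being heterozygous at every SNP (HWE, independence).

    For the three composite SNPs this is the triple-heterozygote route to
    a composite score of 3: the product of 2q(1-q) across SNPs.
    """
    prob = 1.0
    for snp in snps:
        prob *= hwe_genotype_probs(snp.allele2_freq)[1]
    return prob


def unweighted_prs(dosages) -> float:
    """Unweighted composite score: sum of allele-2 dosages (0-2 each).

    Fractional (imputed) dosages yield fractional scores.  Any missing
    dosage makes the score missing (NaN).
    """
    d = np.asarray(dosages, dtype=float)
    if np.any(np.isnan(d)):
        return float("nan")
    if np.any((d < 0) | (d > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    return float(d.sum())


def weighted_prs(
    dosages: dict[str, float],
    weights: dict[str, float],
    frequencies: dict[str, float] | None = None,
) -> float:
    """Weighted polygenic score: sum of weight x dosage over the SNP set.

    A missing dosage contributes its SNP's expected dosage
    (2 x allele-2 frequency) times the weight — mean imputation for the
    score only, never for the genotype matrix.  Raises if the weight and
    dosage sets do not overlap at all.
    """
    common = [r for r in weights if r in dosages]
    if not common:
        raise ValueError("no overlap between weights and dosages")
    score = 0.0
    for rsid, w in weights.items():
        dose = dosages.get(rsid)
        if dose is None or (isinstance(dose, float) and np.isnan(dose)):
            if frequencies is None or rsid not in frequencies:
                continue
            dose = 2.0 * frequencies[rsid]
        score += w * float(dose)
    return score


def read_snp_table(path) -> list[SnpDef]:
    """Read SNP definitions from a delimited table.

    Columns: rsid, gene, chromosome, allele1, allele2, allele2_freq and
    optionally chronotype_or.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for _, r in df.iterrows():
        out.append(
            SnpDef(
                rsid=r["rsid"],
                gene=r["gene"],
                chromosome=str(r["chromosome"]),
                allele1=r["allele1"],
                allele2=r["allele2"],
                allele2_freq=float(r["allele2_freq"]),
                chronotype_or=float(r["chronotype_or"])
                if "chronotype_or" in df.columns and pd.notna(r.get("chronotype_or"))
                else None,
            )
        )
    return out


def read_dosage_matrix(path) -> pd.DataFrame:
    """Read a patient x SNP dosage matrix from delimited text.

    First column is ``patient_id``; remaining columns are rsids holding
    allele-2 dosages in [0, 2].  Missing entries stay NaN (flagged, never
    zero-filled).
    """
    df = pd.read_csv(path, sep=None, engine="python").set_index("patient_id")
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | ((vals >= 0) & (vals <= 2))
    if not ok.all():
        raise ValueError("dosage matrix has entries outside [0, 2]")
    return df


def read_vcf_dosages(path, rsids: list[str] | None = None) -> pd.DataFrame:
    """Read allele-2 dosages from a VCF's DS FORMAT field (needs cyvcf2).

    Falls back to hard-call genotypes (alt-allele counts) for records
    without a DS field.  Returns a patient x SNP DataFrame.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for rec in vcf:
        rid = rec.ID
        if rid is None or (rsids is not None and rid not in rsids):
            continue
        try:
            ds = rec.format("DS")
        except (KeyError, TypeError):
            ds = None
        dose = None if ds is None else np.asarray(ds, dtype=float).reshape(-1)
        if dose is None or np.isnan(dose).all():
            # record carries no dosages; fall back to hard calls
            # (gt_types codes: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt)
            gt = np.asarray(rec.gt_types, dtype=float)
            dose = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        cols[rid] = dose
    return pd.DataFrame(cols, index=pd.Index(samples, name="patient_id"))
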