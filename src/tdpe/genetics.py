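"""Dopamine-receptor genotype handling.

Covers ordinal genotype coding, the BMI + DRD2 summary score, the exact
conditional test of Hardy-Weinberg equilibrium (HWE), and HWE-respecting
genotype simulation.

Ordinal coding follows major-allele dosage: the minor-allele homozygote
is coded 1, the heterozygote 2, the major-allele homozygote 3.  For the
DRD2 promoter -141C Ins/Del (rs1799732) this gives Del/Del=1, Ins/Del=2,
Ins/Ins=3, and for ANKK1/DRD2 Taq1A (rs1800497) A1/A1=1, A1/A2=2,
A2/A2=3.  The DAT and DRD4 tandem repeats are coded analogously by
dosage of the risk repeat (9R for DAT, 7R for DRD4); the map is fully
configurable per locus.

Missing genotypes propagate as missing codes; they are never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "LocusDef",
    "DEFAULT_LOCI",
    "code_genotype",
    "code_genotype_table",
    "summary_score",
    "hwe_exact_test",
    "hwe_table",
    "simulate_genotypes",
    "read_genotype_table",
]


@dataclass(frozen=True)
class LocusDef:
    """A biallelic locus (SNP or two-class repeat polymorphism).

    alleles are ordered (minor, major); the default coding map assigns
    1/2/3 by increasing major-allele dosage.
    """

    name: str
    minor: str
    major: str
    coding_map: dict = field(default=None)  # genotype frozenset-key -> code

    def code(self, genotype: str | None) -> float:
        return code_genotype(self, genotype)

    def _default_code(self, a: str, b: str) -> int:
        dosage = (a == self.major) + (b == self.major)
        return dosage + 1


#: Study loci.  Minor-allele choices follow the common European-ancestry
#: orientation (Taq1A A1 minor, -141C Del minor, COMT Met vs Val, DAT 9R
#: vs 10R, DRD4 7R vs 4R).
DEFAULT_LOCI: dict[str, LocusDef] = {
    "rs1800497": LocusDef("rs1800497", "A1", "A2"),
    "rs1799732": LocusDef("rs1799732", "Del", "Ins"),
    "rs686": LocusDef("rs686", "A", "G"),
    "rs4532": LocusDef("rs4532", "C", "T"),
    "rs5326": LocusDef("rs5326", "T", "C"),
    "rs4680": LocusDef("rs4680", "Met", "Val"),
    "DAT": LocusDef("DAT", "9R", "10R"),
    "DRD4": LocusDef("DRD4", "7R", "4R"),
}


def _parse_call(genotype: str) -> tuple[str, str]:
    for sep in ("/", "|"):
        if sep in genotype:
            a, b = genotype.split(sep, 1)
            return a.strip(), b.strip()
    raise ValueError(f"cannot parse genotype call {genotype!r}; expected 'X/Y'")


def code_genotype(locus: LocusDef, genotype: str | None) -> float:
    """Ordinal code {1, 2, 3} for a genotype call; NaN if missing.

    The code is invariant to allele order within the call (A1/A2 and
    A2/A1 code identically).
    """
    if genotype is None or (isinstance(genotype, float) and math.isnan(genotype)):
        return float("nan")
    if isinstance(genotype, str) and genotype.strip() in ("", ".", "./.", "NA"):
        return float("nan")
    a, b = _parse_call(genotype)
    valid = {locus.minor, locus.major}
    if a not in valid or b not in valid:
        raise ValueError(
            f"{locus.name}: alleles {a}/{b} not in {sorted(valid)}"
        )
    if locus.coding_map is not None:
        return float(locus.coding_map[frozenset((a, b)) if a != b else frozenset((a,))])
    return float(locus._default_code(a, b))


def code_genotype_table(
    table: pd.DataFrame, loci: dict[str, LocusDef] | None = None
) -> pd.DataFrame:
    """Ordinal codes for every locus column present in a genotype table."""
    loci = loci or DEFAULT_LOCI
    out = pd.DataFrame(index=table.index)
    for name, locus in loci.items():
        if name in table.columns:
            out[f"code_{name}"] = table[name].map(lambda g: code_genotype(locus, g))
    return out


def summary_score(bmi: float, code_141: float, code_taq: float) -> float:
    """Raw BMI plus the two DRD2 ordinal codes; NaN if any input missing."""
    if any(pd.isna(v) for v in (bmi, code_141, code_taq)):
        return float("nan")
    return float(bmi) + float(code_141) + float(code_taq)


def _log_het_prob(n_het: int, n: int, n_minor: int) -> float:
    """log P(heterozygote count | total n, minor-allele count) under HWE."""
    n_min_hom = (n_minor - n_het) // 2
    n_maj_hom = n - n_het - n_min_hom
    return (
        gammaln(n + 1)
        - gammaln(n_min_hom + 1)
        - gammaln(n_het + 1)
        - gammaln(n_maj_hom + 1)
        + n_het * math.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_test(n_min_hom: int, n_het: int, n_maj_hom: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts whose conditional probability does not
    exceed that of the observed count.  Symmetric in the homozygote
    labels.  A monomorphic locus has a single attainable configuration
    and returns p = 1.
    """
    counts = (n_min_hom, n_het, n_maj_hom)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("no observations")
    n_minor = 2 * n_min_hom + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # symmetry in allele labels
    parity = n_minor % 2
    hets = np.arange(parity, n_minor + 1, 2)
    logp = np.array([_log_het_prob(int(h), n, n_minor) for h in hets])
    logp -= np.logaddexp.reduce(logp)  # renormalise for numerical safety
    obs = logp[hets == n_het][0]
    p = float(np.exp(logp[logp <= obs + 1e-12]).sum())
    return min(1.0, p)


def hwe_table(
    table: pd.DataFrame, loci: dict[str, LocusDef] | None = None
) -> pd.DataFrame:
    """HWE exact-test p-value per locus column of a genotype table."""
    loci = loci or DEFAULT_LOCI
    rows = []
    for name, locus in loci.items():
        if name not in table.columns:
            continue
        codes = table[name].map(lambda g: code_genotype(locus, g))
        codes = codes.dropna()
        n1 = int((codes == 1).sum())
        n2 = int((codes == 2).sum())
        n3 = int((codes == 3).sum())
        rows.append(
            {
                "locus": name,
                "n_minor_hom": n1,
                "n_het": n2,
                "n_major_hom": n3,
                "p_hwe": hwe_exact_test(n1, n2, n3) if (n1 + n2 + n3) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def hwe_pvalue_null_distribution(n: int, maf: float) -> pd.DataFrame:
    """Exact null distribution of the HWE exact-test p-value.

    Under random mating with minor-allele frequency ``maf`` in a sample
    of ``n`` diploids, the minor-allele count is Binomial(2n, maf) and,
    conditional on it, the heterozygote count follows the exact
    conditional distribution the test is built on.  Because the p-value
    is a deterministic function of (allele count, heterozygote count),
    its full discrete null distribution can be enumerated.  Returns a
    DataFrame with columns ``p`` (sorted support) and ``prob``.

    This is the reference for calibration checks: the exact test is
    discrete and conservative, so its p-values are super-uniform rather
    than exactly uniform, and an empirical sample should be compared
    against this distribution, not against the continuous uniform.
    """
    from scipy.stats import binom

    mass: dict[float, float] = {}
    for n_minor in range(0, 2 * n + 1):
        w = binom.pmf(n_minor, 2 * n, maf)
        if w < 1e-16:
            continue
        nm = min(n_minor, 2 * n - n_minor)
        parity = nm % 2
        hets = np.arange(parity, nm + 1, 2)
        logp = np.array([_log_het_prob(int(h), n, nm) for h in hets])
        logp -= np.logaddexp.reduce(logp)
        probs = np.exp(logp)
        for h, pr in zip(hets, probs):
            min_hom = (nm - int(h)) // 2
            maj_hom = n - int(h) - min_hom
            pval = hwe_exact_test(min_hom, int(h), maj_hom)
            mass[pval] = mass.get(pval, 0.0) + w * pr
    df = pd.DataFrame(sorted(mass.items()), columns=["p", "prob"])
    df["prob"] /= df["prob"].sum()
    return df


def simulate_genotypes(
    n: int, maf: float, locus: LocusDef, seed: int | np.random.Generator = 0
) -> pd.Series:
    """Draw n genotype calls as two independent allele draws (HWE holds
    by construction)."""
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.random((n, 2)) < maf
    calls = []
    for a, b in draws:
        alleles = sorted(
            (locus.minor if a else locus.major, locus.minor if b else locus.major)
        )
        calls.append("/".join(alleles))
    return pd.Series(calls, name=locus.name)


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV genotype table (subject_id + one 'X/Y' column per locus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "subject_id" not in df.columns:
        raise ValueError("genotype table must have a subject_id column")
    return df.set_index("subject_id")
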