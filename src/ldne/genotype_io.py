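"""Reading, writing and normalising SNP genotype data.

Genotypes are held as an individuals x sites allele-dosage matrix
(:class:`GenotypeMatrix`).  Dosages count copies of the alternate allele:
{0, 1, 2} for diploids, {0, 1} for haploids.  Missing calls are masked,
never imputed.  Site coordinates are 1-based; genetic positions are in
centiMorgans.  Only biallelic SNPs are retained.

Supported formats: VCF 4.x (via cyvcf2; plain or bgzipped), PLINK PED+MAP
and TPED(+TFAM).  A genetic map can be approximated from physical positions
with a genome-wide recombination rate (cM/Mb), see
:func:`assign_genetic_positions`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos_bp", "pos_cM", "ref", "alt"]


class GenotypeDataError(ValueError):
    """Raised for unusable or inconsistent genotype input."""


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix with site metadata and a missing-data mask.

    Attributes
    ----------
    dosages : int8 array, shape (n_individuals, n_sites)
        Copies of the alternate allele; value at masked entries is 0.
    missing : bool array, same shape
        True where the genotype call is missing.
    ploidy : int
        1 (haploid) or 2 (unphased diploid).
    sites : DataFrame with columns chrom, pos_bp, pos_cM, ref, alt
        pos_cM is NaN when no genetic position is available.
    """

    dosages: np.ndarray
    missing: np.ndarray
    ploidy: int
    sites: pd.DataFrame
    individuals: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.dosages.shape != self.missing.shape:
            raise GenotypeDataError("dosage and missing-mask shapes differ")
        if self.ploidy not in (1, 2):
            raise GenotypeDataError(f"unsupported ploidy {self.ploidy}")
        if len(self.sites) != self.dosages.shape[1]:
            raise GenotypeDataError("site table length does not match matrix")
        if not self.individuals:
            self.individuals = [f"ind{i}" for i in range(self.dosages.shape[0])]
        called = self.dosages[~self.missing]
        if called.size and (called.min() < 0 or called.max() > self.ploidy):
            raise GenotypeDataError("dosage outside [0, ploidy] at a called entry")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_genetic_positions(self) -> bool:
        return bool(np.isfinite(self.sites["pos_cM"].to_numpy(float)).all()) and self.n_sites > 0

    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of the alternate allele at each site."""
        called = (~self.missing).sum(axis=0) * self.ploidy
        alt = np.where(self.missing, 0, self.dosages).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, alt / called, np.nan)

    def call_rate(self) -> np.ndarray:
        return (~self.missing).mean(axis=0)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, index],
            self.missing[:, index],
            self.ploidy,
            self.sites.iloc[np.atleast_1d(index)].reset_index(drop=True),
            list(self.individuals),
        )

    def drop_chromosome(self, chrom) -> "GenotypeMatrix":
        keep = (self.sites["chrom"].astype(str) != str(chrom)).to_numpy()
        return self.take_sites(np.where(keep)[0])

    def sort_sites(self) -> "GenotypeMatrix":
        order = self.sites.sort_values(["chrom", "pos_bp"], kind="mergesort").index.to_numpy()
        return self.take_sites(order)


def filter_sites(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.9,
    min_chrom_length_bp: float | None = None,
) -> GenotypeMatrix:
    """Apply default site filters: call rate, minor allele frequency and,
    optionally, a minimum chromosome/scaffold length (bp span).

    Dropped counts are logged.  Pass ``maf_min=0`` / ``call_rate_min=0`` to
    disable a filter.
    """
    keep = np.ones(g.n_sites, dtype=bool)
    if call_rate_min > 0:
        keep &= g.call_rate() >= call_rate_min
    if maf_min > 0:
        p = g.allele_frequencies()
        maf = np.minimum(p, 1 - p)
        keep &= np.nan_to_num(maf, nan=-1.0) >= maf_min
    if min_chrom_length_bp is not None:
        spans = g.sites.groupby("chrom")["pos_bp"].agg(lambda s: s.max() - s.min() + 1)
        short = set(spans.index[spans < min_chrom_length_bp])
        if short:
            keep &= ~g.sites["chrom"].isin(short).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_sites: dropped %d of %d sites", n_drop, g.n_sites)
    out = g.take_sites(np.where(keep)[0])
    if out.n_sites == 0:
        raise GenotypeDataError("no sites left after filtering")
    return out


def assign_genetic_positions(g: GenotypeMatrix, rate_cM_per_Mb: float) -> GenotypeMatrix:
    """Fill missing genetic positions from physical positions.

    pos_cM = pos_bp * rate / 1e6.  Sites that already carry a genetic
    position keep it; only absent (NaN) values are filled.
    """
    if not rate_cM_per_Mb > 0:
        raise ValueError(f"recombination rate must be > 0, got {rate_cM_per_Mb}")
    sites = g.sites.copy()
    cm = sites["pos_cM"].to_numpy(float)
    absent = ~np.isfinite(cm)
    cm[absent] = sites["pos_bp"].to_numpy(float)[absent] * rate_cM_per_Mb / 1e6
    sites["pos_cM"] = cm
    return GenotypeMatrix(g.dosages, g.missing, g.ploidy, sites, list(g.individuals))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path,
    ploidy: int = 2,
    maf_min: float = 0.01,
    call_rate_min: float = 0.9,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Phase is ignored; multiallelic and non-SNP records are skipped (counted
    in the log).  ``ploidy=1`` expects haploid genotype calls and fails
    loudly on heterozygous diploid calls rather than silently halving.
    """
    from cyvcf2 import VCF

    if not os.path.exists(str(path)):
        raise GenotypeDataError(f"cannot read VCF: {path}")
    vcf = VCF(str(path), gts012=False)
    individuals = list(vcf.samples)
    n = len(individuals)
    if n == 0:
        raise GenotypeDataError("VCF has no samples")
    dos, miss, rows = [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(v.genotype.array())  # (n, max_ploidy+1); last col = phase
        alleles = gt[:, :-1]
        obs_ploidy = (alleles >= 0).sum(axis=1)
        row_missing = (alleles < 0).any(axis=1)
        if ploidy == 1:
            het = np.zeros(n, dtype=bool)
            if alleles.shape[1] >= 2:
                het = (~row_missing) & (obs_ploidy == 2) & (alleles[:, 0] != alleles[:, 1])
            if het.any():
                raise GenotypeDataError(
                    "haploid read requested but heterozygous diploid calls present"
                )
            d = np.where(alleles[:, 0] > 0, 1, 0)
            row_missing = alleles[:, 0] < 0
        else:
            if (~row_missing & (obs_ploidy != 2)).any():
                raise GenotypeDataError(
                    "mixed or non-diploid ploidy in VCF; use ploidy=1 for haploid data"
                )
            d = np.clip(alleles, 0, None).sum(axis=1)
        dos.append(np.where(row_missing, 0, d).astype(np.int8))
        miss.append(row_missing)
        rows.append((str(v.CHROM), int(v.POS), np.nan, v.REF, v.ALT[0]))
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise GenotypeDataError(f"no usable biallelic SNPs in {path}")
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    g = GenotypeMatrix(np.array(dos).T, np.array(miss).T, ploidy, sites, individuals)
    return filter_sites(g, maf_min, call_rate_min) if (maf_min or call_rate_min) else g


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal unphased VCF (text, uncompressed)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in pd.unique(g.sites["chrom"]):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(i) for i in g.individuals) + "\n")
        for j in range(g.n_sites):
            s = g.sites.iloc[j]
            cols = [str(s.chrom), str(int(s.pos_bp)), f"snp{j}", str(s.ref), str(s.alt),
                    ".", "PASS", ".", "GT"]
            for i in range(g.n_individuals):
                if g.missing[i, j]:
                    cols.append("./." if g.ploidy == 2 else ".")
                elif g.ploidy == 2:
                    d = int(g.dosages[i, j])
                    cols.append(["0/0", "0/1", "1/1"][d])
                else:
                    cols.append(str(int(g.dosages[i, j])))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# PLINK text formats
# ---------------------------------------------------------------------------

def _read_map(map_path) -> pd.DataFrame:
    m = pd.read_csv(map_path, sep=r"\s+", header=None,
                    names=["chrom", "id", "cM", "bp"], dtype={"chrom": str})
    cm = m["cM"].to_numpy(float)
    if np.all(cm == 0):  # degenerate map: genetic positions absent
        cm = np.full(len(m), np.nan)
    return pd.DataFrame({"chrom": m["chrom"], "pos_bp": m["bp"].astype(int),
                         "pos_cM": cm, "id": m["id"]})


def _dosages_from_allele_pairs(a1, a2, ploidy):
    """a1, a2: (n_ind, n_sites) arrays of allele strings ('0' = missing).

    Returns dosages, missing, ref, alt with the alternate allele defined as
    the minor allele (ties broken alphabetically).
    """
    n, m = a1.shape
    dos = np.zeros((n, m), dtype=np.int8)
    miss = np.zeros((n, m), dtype=bool)
    refs, alts, bad = [], [], []
    for j in range(m):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = col[col != "0"]
        alleles, counts = np.unique(obs, return_counts=True)
        if len(alleles) > 2 or len(alleles) == 0:
            bad.append(j)
            refs.append("N")
            alts.append("N")
            continue
        if len(alleles) == 1:
            ref, alt = alleles[0], alleles[0]
        else:
            order = np.lexsort((alleles, -counts))  # major first
            ref, alt = alleles[order[0]], alleles[order[1]]
        refs.append(ref)
        alts.append(alt)
        m1, m2 = a1[:, j] == "0", a2[:, j] == "0"
        if ploidy == 1:
            if not np.array_equal(a1[:, j], a2[:, j]):
                raise GenotypeDataError(
                    "haploid read requested but heterozygous calls present"
                )
            miss[:, j] = m1
            dos[:, j] = (a1[:, j] == alt) & ~m1
        else:
            miss[:, j] = m1 | m2
            dos[:, j] = ((a1[:, j] == alt).astype(np.int8)
                         + (a2[:, j] == alt).astype(np.int8)) * ~(m1 | m2)
    return dos, miss, refs, alts, bad


def read_plink(
    ped_or_tped,
    map_path=None,
    ploidy: int = 2,
    maf_min: float = 0.01,
    call_rate_min: float = 0.9,
) -> GenotypeMatrix:
    """Read PLINK PED+MAP or TPED(+TFAM) text genotypes.

    PED carries no genetic positions, so a MAP file is required with it;
    its cM column is used when non-zero, else genetic positions are marked
    absent (fill them later with :func:`assign_genetic_positions`).
    """
    path = str(ped_or_tped)
    if path.endswith(".tped"):
        g = _read_tped(path, ploidy)
    else:
        if map_path is None:
            base, _ = os.path.splitext(path)
            map_path = base + ".map"
        g = _read_ped(path, map_path, ploidy)
    return filter_sites(g, maf_min, call_rate_min) if (maf_min or call_rate_min) else g


def _read_ped(ped_path, map_path, ploidy):
    sites = _read_map(map_path)
    ids, pairs = [], []
    with open(ped_path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * len(sites):
                raise GenotypeDataError(
                    f"PED row with {len(tok)} fields inconsistent with MAP "
                    f"({len(sites)} sites)"
                )
            ids.append(tok[1])
            pairs.append(tok[6:])
    if not ids:
        raise GenotypeDataError(f"empty PED file {ped_path}")
    arr = np.array(pairs)
    a1, a2 = arr[:, 0::2], arr[:, 1::2]
    dos, miss, refs, alts, bad = _dosages_from_allele_pairs(a1, a2, ploidy)
    sites = sites.assign(ref=refs, alt=alts)[SITE_COLUMNS]
    g = GenotypeMatrix(dos, miss, ploidy, sites, ids)
    if bad:
        logger.info("read_plink: dropped %d non-biallelic sites", len(bad))
        keep = np.setdiff1d(np.arange(g.n_sites), bad)
        g = g.take_sites(keep)
    return g


def _read_tped(tped_path, ploidy):
    tfam = os.path.splitext(tped_path)[0] + ".tfam"
    ids = None
    if os.path.exists(tfam):
        ids = [ln.split()[1] for ln in open(tfam) if ln.split()]
    rows, a1c, a2c = [], [], []
    with open(tped_path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            rows.append(tok[:4])
            al = np.array(tok[4:])
            a1c.append(al[0::2])
            a2c.append(al[1::2])
    if not rows:
        raise GenotypeDataError(f"empty TPED file {tped_path}")
    m = pd.DataFrame(rows, columns=["chrom", "id", "cM", "bp"])
    cm = m["cM"].to_numpy(float)
    if np.all(cm == 0):
        cm = np.full(len(m), np.nan)
    a1 = np.array(a1c).T  # individuals x sites
    a2 = np.array(a2c).T
    if len({len(r) for r in a1c}) != 1:
        raise GenotypeDataError("ragged TPED rows")
    dos, miss, refs, alts, bad = _dosages_from_allele_pairs(a1, a2, ploidy)
    sites = pd.DataFrame({"chrom": m["chrom"].astype(str), "pos_bp": m["bp"].astype(int),
                          "pos_cM": cm, "ref": refs, "alt": alts})
    g = GenotypeMatrix(dos, miss, ploidy, sites, ids or [])
    if bad:
        logger.info("read_plink: dropped %d non-biallelic sites", len(bad))
        g = g.take_sites(np.setdiff1d(np.arange(g.n_sites), bad))
    return g


def write_tped(g: GenotypeMatrix, prefix) -> None:
    """Write TPED + TFAM (alleles coded by ref/alt labels; missing = 0)."""
    with open(str(prefix) + ".tfam", "w") as fh:
        for ind in g.individuals:
            fh.write(f"{ind} {ind} 0 0 0 -9\n")
    with open(str(prefix) + ".tped", "w") as fh:
        cm = g.sites["pos_cM"].to_numpy(float)
        for j in range(g.n_sites):
            s = g.sites.iloc[j]
            cmj = 0.0 if not np.isfinite(cm[j]) else cm[j]
            cols = [str(s.chrom), f"snp{j}", repr(float(cmj)), str(int(s.pos_bp))]
            ref, alt = str(s.ref), str(s.alt)
            for i in range(g.n_individuals):
                if g.missing[i, j]:
                    cols += ["0", "0"]
                else:
                    d = int(g.dosages[i, j])
                    if g.ploidy == 1:
                        a = alt if d else ref
                        cols += [a, a]
                    else:
                        cols += [alt if d >= 1 else ref, alt if d == 2 else ref]
            fh.write(" ".join(cols) + "\n")
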