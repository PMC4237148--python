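"""Genotype input, filtering and population metadata.

The analysis operates on a complete-case matrix of allele dosages
(count of the VCF ALT allele per diploid individual, 0/1/2) for
biallelic SNPs.  Filtering reproduces a conservative RAD-seq style
protocol: drop indels and multi-allelic records, sites whose mean
coverage falls below a threshold, sites with any genotype quality
below a threshold, sites with any missing call, and sites that are
monomorphic across the remaining samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel dosage for an uncalled genotype


class EmptyFilterResult(ValueError):
    """Raised when no locus survives filtering."""


@dataclass
class GenotypeMatrix:
    """Diploid allele-dosage matrix (samples x biallelic loci).

    Attributes
    ----------
    samples:
        Ordered sample identifiers.
    loci:
        One row per locus with columns ``id, contig, pos, ref, alt,
        is_snp, is_biallelic, mean_dp`` (``mean_dp`` is NaN when the
        source carried no depth annotation).  ``pos`` is 1-based.
    dosage:
        ``int8`` array of shape ``(n_samples, n_loci)``; ``-1`` marks a
        missing call.
    gq:
        Optional per-genotype quality array of the same shape (NaN when
        absent).
    """

    samples: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray
    gq: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset loci by integer positions or boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index].copy(),
            gq=None if self.gq is None else self.gq[:, index].copy(),
        )

    def locus_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {lid: i for i, lid in enumerate(self.loci["id"])}
        return np.array([lookup[i] for i in ids], dtype=int)


@dataclass
class PopulationMap:
    """Sample -> population and population -> ecotype assignment."""

    table: pd.DataFrame  # columns: sample, population, ecotype

    def __post_init__(self) -> None:
        required = {"sample", "population", "ecotype"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"population map needs columns {sorted(required)}")

    @property
    def populations(self) -> list[str]:
        """Populations in order of first appearance."""
        return list(dict.fromkeys(self.table["population"]))

    @property
    def sizes(self) -> dict[str, int]:
        return self.table["population"].value_counts().reindex(self.populations).to_dict()

    @property
    def ecotype_of(self) -> dict[str, str]:
        return dict(zip(self.table["population"], self.table["ecotype"]))

    def ecotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["ecotype"]))

    def populations_of_ecotype(self, ecotype: str) -> list[str]:
        return [p for p in self.populations if self.ecotype_of[p] == ecotype]

    def samples_of(self, population: str) -> list[str]:
        sub = self.table[self.table["population"] == population]
        return list(sub["sample"])

    def pop_codes(self, samples: Sequence[str]) -> np.ndarray:
        """Integer population index (order of :attr:`populations`) per sample."""
        pop_of = dict(zip(self.table["sample"], self.table["population"]))
        order = {p: i for i, p in enumerate(self.populations)}
        return np.array([order[pop_of[s]] for s in samples], dtype=int)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    All records are retained; non-SNP (indel) and multi-allelic records
    are flagged so the filter stage can count them.  Missing genotypes
    are encoded as dosage ``-1``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        reader = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(reader.samples)
    rows = []
    dosages = []
    quals = []
    any_gq = False
    for i, v in enumerate(reader):
        try:
            alt = v.ALT[0] if v.ALT else "."
            is_biallelic = len(v.ALT) == 1
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
            gt = np.asarray(v.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            try:
                depths = v.format("DP")
            except KeyError:
                depths = None
            if depths is not None:
                d = np.asarray(depths, dtype=float).ravel()
                mean_dp = float(np.mean(d[d >= 0])) if np.any(d >= 0) else np.nan
            else:
                info_dp = v.INFO.get("DP")
                mean_dp = float(info_dp) / len(samples) if info_dp is not None else np.nan
            gq = v.gt_quals
            if gq is not None:
                gq = np.asarray(gq, dtype=float)
                gq[gq < 0] = np.nan
                if np.any(np.isfinite(gq)):
                    any_gq = True
            else:
                gq = np.full(len(samples), np.nan)
        except Exception as exc:
            raise ValueError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
        rows.append(
            {
                "id": f"{v.CHROM}_{v.POS}",
                "contig": v.CHROM,
                "pos": int(v.POS),
                "ref": v.REF,
                "alt": alt,
                "is_snp": bool(v.is_snp),
                "is_biallelic": is_biallelic,
                "mean_dp": mean_dp,
            }
        )
        dosages.append(gt)
        quals.append(gq)

    loci = pd.DataFrame(
        rows,
        columns=["id", "contig", "pos", "ref", "alt", "is_snp", "is_biallelic", "mean_dp"],
    )
    dosage = (
        np.stack(dosages, axis=1) if dosages else np.empty((len(samples), 0), dtype=np.int8)
    )
    gq_arr = np.stack(quals, axis=1) if (quals and any_gq) else None
    return GenotypeMatrix(samples=samples, loci=loci, dosage=dosage, gq=gq_arr)


def filter_snps(
    matrix: GenotypeMatrix,
    min_mean_coverage: float = 20.0,
    min_genotype_quality: float = 20.0,
    drop_missing: bool = True,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the SNP filtering protocol; return the kept matrix and a removal ledger.

    Rules, applied in order (each dropped locus is attributed to the
    first rule it fails): non-SNP (indel), multi-allelic, mean coverage
    below ``min_mean_coverage`` (skipped with a warning when no depth
    annotation is present), any genotype quality below
    ``min_genotype_quality`` (skipped when absent), any missing call,
    monomorphic across all samples.
    """
    ledger = {"indel": 0, "multiallelic": 0, "coverage": 0, "quality": 0, "missing": 0, "monomorphic": 0}
    n = matrix.n_loci
    keep = np.ones(n, dtype=bool)

    is_snp = matrix.loci["is_snp"].to_numpy(dtype=bool)
    drop = keep & ~is_snp
    ledger["indel"] = int(drop.sum())
    keep &= is_snp

    is_bi = matrix.loci["is_biallelic"].to_numpy(dtype=bool)
    drop = keep & ~is_bi
    ledger["multiallelic"] = int(drop.sum())
    keep &= is_bi

    mean_dp = matrix.loci["mean_dp"].to_numpy(dtype=float)
    if np.all(np.isnan(mean_dp)):
        logger.warning("no coverage annotation present; coverage filter skipped")
    else:
        ok = np.isnan(mean_dp) | (mean_dp >= min_mean_coverage)
        drop = keep & ~ok
        ledger["coverage"] = int(drop.sum())
        keep &= ok

    if matrix.gq is None:
        logger.warning("no genotype-quality annotation present; GQ filter skipped")
    else:
        bad = np.nanmin(np.where(np.isnan(matrix.gq), np.inf, matrix.gq), axis=0) < min_genotype_quality
        drop = keep & bad
        ledger["quality"] = int(drop.sum())
        keep &= ~bad

    if drop_missing:
        has_missing = (matrix.dosage == MISSING).any(axis=0)
        drop = keep & has_missing
        ledger["missing"] = int(drop.sum())
        keep &= ~has_missing

    # non-variable loci carry no information for differentiation
    d = np.where(matrix.dosage == MISSING, np.nan, matrix.dosage.astype(float))
    with np.errstate(invalid="ignore"):
        mono = (np.nanmin(d, axis=0) == np.nanmax(d, axis=0)) & np.isin(np.nanmax(d, axis=0), (0.0, 2.0))
    drop = keep & mono
    ledger["monomorphic"] = int(drop.sum())
    keep &= ~mono

    if not keep.any():
        raise EmptyFilterResult("no locus survived filtering")
    return matrix.take_loci(keep), ledger


def read_popmap(path: str | Path, matrix: GenotypeMatrix) -> PopulationMap:
    """Read and validate a sample/population/ecotype TSV against a matrix."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.empty:
        raise ValueError(f"population map {path} is empty")
    if list(table.columns[:3]) != ["sample", "population", "ecotype"]:
        # accept header-less three-column files
        table = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["sample", "population", "ecotype"])
    dups = table["sample"][table["sample"].duplicated()].tolist()
    if dups:
        raise ValueError(f"duplicate sample rows in population map: {dups}")
    mapped = set(table["sample"])
    missing = [s for s in matrix.samples if s not in mapped]
    if missing:
        raise ValueError(f"samples missing from population map: {missing}")
    extra = [s for s in table["sample"] if s not in set(matrix.samples)]
    if extra:
        raise ValueError(f"population map samples absent from genotype data: {extra}")
    # preserve the matrix sample order
    table = table.set_index("sample").loc[matrix.samples].reset_index()
    return PopulationMap(table=table)
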