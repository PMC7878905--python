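"""Genotype handling: allele statistics, qualifying variants, gene groups.

Gene-based rare-variant tests aggregate "qualifying" variants: in-sample
minor allele frequency (MAF) strictly below 1% and an annotated consequence
likely to alter the gene product (nonsynonymous, stop gain/loss, splicing).
Genes are retained when they carry at least 2 qualifying variants with a
cumulative minor allele count (MAC) of at least 10.

All allele statistics are computed in-sample after minor-allele orientation:
if the alternate allele frequency exceeds 0.5, dosages are flipped to
``2 - d`` so that dosage counts always refer to the minor allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

QUALIFYING_CLASSES = frozenset({"nonsynonymous", "stop gain", "stop loss", "splicing"})
CONSEQUENCE_CLASSES = frozenset(
    {"nonsynonymous", "stop gain", "stop loss", "splicing", "synonymous", "other"}
)

__all__ = [
    "GenotypeData",
    "GeneGroup",
    "QUALIFYING_CLASSES",
    "allele_stats",
    "qualify_variants",
    "build_gene_groups",
    "mean_impute",
    "carrier_status",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_annotation_tsv",
]


def allele_stats(dosages: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Minor-allele frequency and count for one variant, with orientation.

    Returns ``(maf, mac, oriented_dosages)``.  Missing entries (NaN) are
    excluded from the denominator; if the alternate-allele frequency exceeds
    0.5 the dosages are flipped to ``2 - d`` first.
    """
    d = np.asarray(dosages, dtype=float)
    obs = ~np.isnan(d)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("all dosages missing")
    freq = d[obs].sum() / (2 * n_obs)
    if freq > 0.5:
        d = np.where(obs, 2.0 - d, np.nan)
    mac = int(round(d[obs].sum()))
    return mac / (2 * n_obs), mac, d


@dataclass
class GenotypeData:
    """Samples x variants dosage matrix plus in-sample allele statistics.

    ``dosages`` holds minor-allele counts in {0, 1, 2} (NaN = missing) after
    orientation; ``variants`` is a DataFrame indexed by variant id with
    columns chrom, pos, ref, alt, maf, mac.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray  # shape (n_samples, n_variants), minor-oriented

    @classmethod
    def from_raw(
        cls, samples: Sequence[str], variants: pd.DataFrame, dosages: np.ndarray
    ) -> "GenotypeData":
        """Orient each variant to the minor allele and compute MAF/MAC."""
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(samples), len(variants)):
            raise ValueError("dosage matrix shape does not match samples x variants")
        variants = variants.copy()
        mafs, macs = [], []
        for j in range(dosages.shape[1]):
            maf, mac, oriented = allele_stats(dosages[:, j])
            dosages[:, j] = oriented
            mafs.append(maf)
            macs.append(mac)
        variants["maf"] = mafs
        variants["mac"] = macs
        return cls(list(samples), variants, dosages)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.samples, columns=self.variants.index)

    def subset(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Dosage sub-matrix for the given variant ids (columns in that order)."""
        idx = [self.variants.index.get_loc(v) for v in variant_ids]
        return self.dosages[:, idx]


@dataclass
class GeneGroup:
    """A gene's qualifying-variant set with aggregate allele statistics."""

    gene: str
    variant_ids: list[str]
    total_mac: int
    cumulative_maf: float


def qualify_variants(
    genotypes: GenotypeData,
    annotations: pd.DataFrame,
    maf_max: float = 0.01,
    classes: Iterable[str] = QUALIFYING_CLASSES,
) -> dict[str, list[str]]:
    """Qualifying variant ids per gene.

    A variant qualifies for a gene iff its in-sample MAF is strictly below
    ``maf_max`` and its annotated consequence for that gene is in ``classes``.
    ``annotations`` has columns variant_id, gene, consequence; a variant
    annotated to several genes contributes to each.
    """
    classes = set(classes)
    maf = genotypes.variants["maf"]
    known = annotations["variant_id"].isin(genotypes.variants.index)
    if not known.all():
        unknown = annotations.loc[~known, "variant_id"].unique()[:5]
        raise ValueError(f"annotations reference unknown variants, e.g. {list(unknown)}")
    out: dict[str, list[str]] = {}
    for row in annotations.itertuples(index=False):
        if row.consequence in classes and maf[row.variant_id] < maf_max:
            out.setdefault(row.gene, []).append(row.variant_id)
    return out


def build_gene_groups(
    qualifying: dict[str, list[str]],
    genotypes: GenotypeData,
    min_mac: int = 10,
    min_variants: int = 2,
) -> list[GeneGroup]:
    """Gene groups passing the MAC and variant-count filters.

    Total MAC is the sum of member MACs and cumulative MAF the sum of member
    MAFs, matching the reporting convention of the per-gene result tables.
    """
    groups = []
    for gene in sorted(qualifying):
        vids = qualifying[gene]
        if len(vids) < min_variants:
            continue
        total_mac = int(genotypes.variants.loc[vids, "mac"].sum())
        if total_mac < min_mac:
            continue
        cum_maf = float(genotypes.variants.loc[vids, "maf"].sum())
        groups.append(GeneGroup(gene, list(vids), total_mac, cum_maf))
    return groups


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant observed mean dosage."""
    d = np.asarray(dosages, dtype=float).copy()
    if d.ndim == 1:
        d = d[:, None]
        squeeze = True
    else:
        squeeze = False
    for j in range(d.shape[1]):
        col = d[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            raise ValueError(f"variant column {j} is fully missing")
        col[~obs] = col[obs].mean()
    return d[:, 0] if squeeze else d


CARRIER_CATEGORIES = ("non-carrier", "het-single", "het-multiple", "homozygous")


def carrier_status(
    genotypes: GenotypeData, group: GeneGroup
) -> tuple[pd.Series, int, float]:
    """Per-sample carrier category for a gene group, plus carrier count/fraction.

    Categories: ``homozygous`` if any member dosage equals 2; else
    ``het-multiple`` if two or more member dosages equal 1; else
    ``het-single`` if exactly one; else ``non-carrier``.  Missing dosages
    count as non-carrying.  The carrier fraction is carriers of >= 1
    qualifying allele over all samples.
    """
    G = genotypes.subset(group.variant_ids)
    with np.errstate(invalid="ignore"):
        n_hom = (G == 2).sum(axis=1)
        n_het = (G == 1).sum(axis=1)
    cat = np.where(
        n_hom >= 1,
        "homozygous",
        np.where(n_het >= 2, "het-multiple", np.where(n_het == 1, "het-single", "non-carrier")),
    )
    status = pd.Series(cat, index=genotypes.samples, name=group.gene)
    n_carriers = int((status != "non-carrier").sum())
    return status, n_carriers, n_carriers / len(status)


# ---------------------------------------------------------------------------
# I/O

def write_vcf(genotypes: GenotypeData, path: str | Path) -> None:
    """Write biallelic GT-only VCF v4.2 (1-based positions, './.' = missing).

    Dosages are written against the ALT allele as stored, i.e. the
    minor-oriented dosage; orientation is recovered on read via
    :func:`GenotypeData.from_raw`, to which MAF/MAC are invariant.
    """
    chroms = sorted(set(genotypes.variants["chrom"].astype(str)), key=str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=uromet\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, (vid, row) in enumerate(genotypes.variants.iterrows()):
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeData:
    """Read a biallelic GT-only VCF into a :class:`GenotypeData`.

    Multiallelic records are rejected with a clear error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records, dosage_cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS} ({v.REF}->{v.ALT}); "
                "split into biallelic records first"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = v.gt_types
        d = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        records.append({"variant_id": vid, "chrom": v.CHROM, "pos": v.POS,
                        "ref": v.REF, "alt": v.ALT[0]})
        dosage_cols.append(d)
    variants = pd.DataFrame(records).set_index("variant_id")
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    return GenotypeData.from_raw(samples, variants, dosages)


def write_dosage_tsv(genotypes: GenotypeData, path: str | Path) -> None:
    genotypes.dosage_frame().to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_dosage_tsv(path: str | Path, variants: pd.DataFrame | None = None) -> GenotypeData:
    """Read a samples x variants dosage TSV (empty cell = missing).

    If ``variants`` metadata is not given, placeholder chrom/pos/ref/alt are
    synthesized (dosage-matrix inputs carry no coordinates).
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if variants is None:
        variants = pd.DataFrame(
            {
                "variant_id": df.columns,
                "chrom": "NA",
                "pos": np.arange(1, df.shape[1] + 1),
                "ref": "N",
                "alt": "N",
            }
        ).set_index("variant_id")
    return GenotypeData.from_raw(list(df.index), variants, df.to_numpy(dtype=float))


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene", "consequence"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    bad = set(ann["consequence"]) - CONSEQUENCE_CLASSES
    if bad:
        raise ValueError(f"unknown consequence classes: {sorted(bad)}")
    return ann
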