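"""Readers and writers for the pipeline's on-disk formats.

Genotype matrices travel as TSV (individuals x markers, codes {0,1,2},
missing empty/NA) or as VCF with pseudo-diploid GT fields (0/0, 0/1, 1/1,
./.) and the defining tag sequences in INFO; phenotypes and trial tables as
TSV.  VCF goes through pysam, FASTQ through Biopython (see simdata/calling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import MISSING, GenotypeMatrix

__all__ = [
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_vcf",
    "read_vcf",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
]


def write_genotype_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.codes, index=G.sample_ids, columns=G.marker_names)
    df = df.where(df != MISSING, other=pd.NA)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    codes = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(codes=codes, sample_ids=[str(s) for s in df.index],
                          marker_names=[str(c) for c in df.columns])


def write_phenotype_tsv(values, sample_ids, path, column: str = "phenotype") -> None:
    pd.DataFrame({"sample_id": sample_ids, column: np.asarray(values)}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype_tsv(path, column: str = "phenotype") -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return df.set_index("sample_id")[column]


_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write pseudo-diploid genotypes as VCF.

    Positions are 1-based; unaligned markers sit on chromosome "N" with
    sequential positions.  Tag-pair sequences, when known, are carried in
    INFO fields TAGR/TAGA.
    """
    import pysam

    info = G.marker_info
    header = pysam.VariantHeader()
    header.add_meta("source", "polygs")
    header.info.add("TAGR", 1, "String", "Reference 64-bp tag sequence")
    header.info.add("TAGA", 1, "String", "Alternate 64-bp tag sequence")
    header.formats.add("GT", 1, "String", "Pseudo-diploid genotype")
    chroms = ["N"]
    if info is not None and "chrom" in info.columns:
        chroms = sorted(set(info["chrom"].astype(str))) or ["N"]
        if "N" not in chroms:
            chroms.append("N")
    for c in chroms:
        header.contigs.add(c, length=2**29)
    for s in G.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        fallback_pos = 0
        for j, name in enumerate(G.marker_names):
            row = info.loc[name] if info is not None and name in info.index else None
            chrom = str(row["chrom"]) if row is not None and "chrom" in row else "N"
            if row is not None and "pos" in row and not pd.isna(row.get("pos", np.nan)):
                pos = int(row["pos"])
            else:
                fallback_pos += 1
                pos = fallback_pos
            ref = str(row["ref_allele"]) if row is not None and "ref_allele" in row else "A"
            alt = str(row["alt_allele"]) if row is not None and "alt_allele" in row else "C"
            rec = vf.new_record(contig=chrom, start=pos - 1, stop=pos,
                                alleles=(ref, alt), id=name)
            if row is not None and "tag_ref" in row:
                rec.info["TAGR"] = str(row["tag_ref"])
                rec.info["TAGA"] = str(row["tag_alt"])
            for i, s in enumerate(G.sample_ids):
                rec.samples[s]["GT"] = _GT[int(G.codes[i, j])]
            vf.write(rec)


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into pseudo-diploid {0,1,2,missing} codes."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        names, cols, rows = [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            names.append(rec.id or f"{rec.chrom}_{rec.pos}")
            col = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col.append(MISSING)
                else:
                    col.append(int(sum(gt)))
            cols.append(col)
            rows.append({"marker": names[-1], "chrom": rec.chrom, "pos": rec.pos})
    codes = np.array(cols, dtype=np.int8).T if cols else np.zeros((len(samples), 0), np.int8)
    info = pd.DataFrame(rows).set_index("marker") if rows else None
    return GenotypeMatrix(codes=codes, sample_ids=samples, marker_names=names,
                          marker_info=info)
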