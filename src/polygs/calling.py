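"""Reference-free tag-pair SNP discovery and genotype calling for GBS reads.

The pipeline mirrors reference-free GBS calling for species without a genome
assembly: barcoded single-end reads are demultiplexed, checked for the
restriction-site remnant, trimmed to 64 bp and aggregated into per-sample tag
counts; tags supported by at least ``min_total_reads`` reads across all
individuals are scanned for pairs differing at exactly one base; each
reciprocal-unique pair defines one biallelic SNP, genotyped per individual
from the read-count distribution over the two tags.  All heterozygous
autotetraploid dosage classes (Aaaa, AAaa, AAAa) are collapsed to a single
pseudo-diploid heterozygote code 1.

Discovery can run per cohort (``separate``) or on the pooled reads of several
cohorts (``joint``); joint discovery yields identical SNP names across
cohorts, which is what makes cross-cohort marker intersection possible
without a reference genome.
"""

from __future__ import annotations

import hashlib
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import MISSING, GenotypeMatrix, _maybe_gz

__all__ = [
    "TagCountTable",
    "SnpCall",
    "demultiplex_trim",
    "discover_tag_pairs",
    "call_genotypes",
    "call_snps",
]

TAG_LEN = 64

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "N": "ACGT",
}


class KeyTableError(ValueError):
    """Malformed barcode key table."""


@dataclass
class TagCountTable:
    """Per-sample read counts over 64-bp sequence tags."""

    counts: pd.DataFrame  # samples x tags, non-negative ints

    def __post_init__(self) -> None:
        if any(len(t) != TAG_LEN for t in self.counts.columns):
            raise ValueError(f"all tags must be {TAG_LEN} bp")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tags(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self) -> pd.Series:
        """Reads per tag summed over all individuals."""
        return self.counts.sum(axis=0)

    @classmethod
    def merge(cls, tables: list["TagCountTable"]) -> "TagCountTable":
        """Pool several cohorts into one table (outer join on tags)."""
        ids = [s for t in tables for s in t.sample_ids]
        if len(set(ids)) != len(ids):
            raise KeyTableError("sample-id collision between cohorts")
        merged = pd.concat([t.counts for t in tables], axis=0).fillna(0).astype(np.int64)
        return cls(merged)


@dataclass
class SnpCall:
    """One biallelic SNP defined by a 1-bp-apart tag pair."""

    name: str
    tag_query: str
    tag_hit: str
    variant_position: int  # 0-based offset within the tag
    genotypes: np.ndarray  # {0,1,2,MISSING} per individual


def _remnant_matches(seq: str, remnant: str) -> bool:
    if len(seq) < len(remnant):
        return False
    return all(base in _IUPAC.get(code, "") for base, code in zip(seq, remnant))


def read_key_table(path) -> pd.DataFrame:
    key = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode", "sample_id"}
    if not required.issubset(key.columns):
        raise KeyTableError(f"key table must have columns {sorted(required)}")
    lane = key["flowcell_lane"] if "flowcell_lane" in key.columns else pd.Series(["?"] * len(key))
    if key.groupby(lane)["barcode"].apply(lambda s: s.duplicated().any()).any():
        raise KeyTableError("duplicate barcodes within a lane")
    return key


def demultiplex_trim(fastq_path, key_table, cutsite_remnant: str = "CWGC") -> TagCountTable:
    """Demultiplex barcoded GBS reads and aggregate them into tag counts.

    A read is retained iff it begins with a known barcode immediately followed
    by the cut-site remnant (IUPAC codes allowed, default ApeKI ``CWGC``) and,
    after barcode removal, still carries at least 64 bases free of ambiguous
    calls.  Retained reads are trimmed to 64 bp; identical trimmed reads are
    grouped into one tag per sample.
    """
    from Bio import SeqIO

    if isinstance(key_table, (str, bytes)) or hasattr(key_table, "__fspath__"):
        key_table = read_key_table(key_table)
    barcode_to_sample = dict(zip(key_table["barcode"], key_table["sample_id"]))
    if len(barcode_to_sample) != len(key_table):
        raise KeyTableError("duplicate barcodes in key table")
    by_len = sorted({len(b) for b in barcode_to_sample}, reverse=True)

    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    n_reads = 0
    with _maybe_gz(fastq_path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            n_reads += 1
            seq = str(rec.seq).upper()
            sample = None
            for blen in by_len:  # longest-match barcode lookup
                bc = seq[:blen]
                if bc in barcode_to_sample:
                    sample = barcode_to_sample[bc]
                    seq = seq[blen:]
                    break
            if sample is None or not _remnant_matches(seq, cutsite_remnant):
                continue
            tag = seq[:TAG_LEN]
            if len(tag) < TAG_LEN or any(b not in "ACGT" for b in tag):
                continue
            counts[sample][tag] += 1
    if n_reads == 0:
        warnings.warn("empty FASTQ: tag count table will be empty")
    samples = list(key_table["sample_id"])
    df = pd.DataFrame.from_dict(counts, orient="index").reindex(samples).fillna(0).astype(np.int64)
    df = df[sorted(df.columns)] if len(df.columns) else df
    return TagCountTable(df)


def _hamming1_partner_scan(tags: list[str]) -> dict[str, set[str]]:
    """All 1-bp-apart tag pairs via masked-position hashing (O(tags x 64))."""
    partners: dict[str, set[str]] = defaultdict(set)
    for pos in range(TAG_LEN):
        bucket: dict[str, list[str]] = defaultdict(list)
        for t in tags:
            bucket[t[:pos] + t[pos + 1 :]].append(t)
        for group in bucket.values():
            if len(group) < 2:
                continue
            for i, a in enumerate(group):
                for b in group[i + 1 :]:
                    if a != b:
                        partners[a].add(b)
                        partners[b].add(a)
    return partners


def discover_tag_pairs(
    table: TagCountTable, min_total_reads: int = 10
) -> list[tuple[str, str]]:
    """Find reciprocal-unique tag pairs differing at exactly one base.

    Only tags with ``min_total_reads`` or more reads summed over all
    individuals enter pairing.  Tags belonging to more than one candidate
    pair (paralog-like networks) are discarded entirely; only pairs in which
    each tag's sole 1-bp neighbour is the other member are emitted.
    """
    totals = table.total_reads()
    kept = [t for t in table.tags if totals[t] >= min_total_reads]
    partners = _hamming1_partner_scan(kept)
    pairs = []
    for tag, nb in partners.items():
        if len(nb) != 1:
            continue
        other = next(iter(nb))
        if len(partners[other]) != 1:
            continue
        if tag < other:  # emit each reciprocal pair once
            pairs.append((tag, other))
    pairs.sort()
    return pairs


def snp_name(tag_a: str, tag_b: str) -> str:
    """Stable content-derived SNP identifier, symmetric in the pair."""
    lo, hi = sorted((tag_a, tag_b))
    return "TP" + hashlib.sha1(f"{lo}|{hi}".encode()).hexdigest()[:12]


def call_genotypes(
    reads_a: np.ndarray,
    reads_b: np.ndarray,
    min_depth: int = 3,
    het_min_minor_reads: int = 2,
) -> np.ndarray:
    """Genotype a tag pair from per-individual read counts.

    Codes count the B (alternate) allele on a pseudo-diploid scale: total
    depth below ``min_depth`` is missing; both alleles observed with at least
    ``het_min_minor_reads`` reads each is the collapsed heterozygote 1;
    otherwise the homozygote of the majority allele (0 for A, 2 for B).
    """
    reads_a = np.asarray(reads_a)
    reads_b = np.asarray(reads_b)
    if np.any(reads_a < 0) or np.any(reads_b < 0):
        raise ValueError("read counts must be non-negative")
    total = reads_a + reads_b
    minor = np.minimum(reads_a, reads_b)
    codes = np.where(reads_b > reads_a, 2, 0)
    codes = np.where(minor >= het_min_minor_reads, 1, codes)
    return np.where(total < min_depth, MISSING, codes).astype(np.int8)


def _call_from_table(
    table: TagCountTable,
    pairs: list[tuple[str, str]],
    min_depth: int,
    het_min_minor_reads: int,
) -> GenotypeMatrix:
    calls = []
    names = []
    info_rows = []
    for tag_a, tag_b in pairs:
        ca = table.counts[tag_a].to_numpy()
        cb = table.counts[tag_b].to_numpy()
        g = call_genotypes(ca, cb, min_depth, het_min_minor_reads)
        pos = next(i for i, (x, y) in enumerate(zip(tag_a, tag_b)) if x != y)
        name = snp_name(tag_a, tag_b)
        names.append(name)
        calls.append(g)
        info_rows.append(
            {
                "marker": name,
                "tag_ref": tag_a,
                "tag_alt": tag_b,
                "snp_pos": pos,
                "ref_allele": tag_a[pos],
                "alt_allele": tag_b[pos],
                "chrom": "N",
            }
        )
    codes = (
        np.column_stack(calls)
        if calls
        else np.zeros((len(table.sample_ids), 0), dtype=np.int8)
    )
    info = pd.DataFrame(info_rows).set_index("marker") if info_rows else None
    return GenotypeMatrix(
        codes=codes, sample_ids=table.sample_ids, marker_names=names, marker_info=info
    )


def call_snps(
    tables: TagCountTable | list[TagCountTable],
    mode: str = "separate",
    min_total_reads: int = 10,
    min_depth: int = 3,
    het_min_minor_reads: int = 2,
) -> list[GenotypeMatrix]:
    """Discover and call SNPs for one or more cohorts.

    ``separate`` runs discovery and calling independently per cohort;
    ``joint`` pools the reads of all cohorts for discovery and calling, then
    splits the genotype matrix back into the cohorts, so every cohort reports
    the same SNP set under the same content-derived names.
    """
    if isinstance(tables, TagCountTable):
        tables = [tables]
    if mode not in ("separate", "joint"):
        raise ValueError(f"unknown calling mode {mode!r}")
    if mode == "separate" or len(tables) == 1:
        out = []
        for t in tables:
            pairs = discover_tag_pairs(t, min_total_reads)
            out.append(_call_from_table(t, pairs, min_depth, het_min_minor_reads))
        return out
    pooled = TagCountTable.merge(tables)
    pairs = discover_tag_pairs(pooled, min_total_reads)
    joint = _call_from_table(pooled, pairs, min_depth, het_min_minor_reads)
    out = []
    offset = 0
    for t in tables:
        n = len(t.sample_ids)
        out.append(joint.select_individuals(np.arange(offset, offset + n)))
        offset += n
    return out


def align_to_panel(called: GenotypeMatrix, panel: pd.DataFrame) -> GenotypeMatrix:
    """Re-express called genotypes on a simulated tag panel's allele coding.

    Matches each called SNP to the panel marker carrying the same tag pair
    and flips codes (2 - code) where the call's A/B orientation is reversed
    relative to the panel's ref/alt, so that concordance with the simulated
    matrix is computed on a common allele coding.  SNPs with no panel match
    are dropped; output columns are labelled by panel marker name.
    """
    by_pair = {
        tuple(sorted((row["tag_ref"], row["tag_alt"]))): (name, row["tag_ref"])
        for name, row in panel.iterrows()
    }
    keep, names, flips = [], [], []
    info = called.marker_info
    for k, snp in enumerate(called.marker_names):
        ta, tb = info.loc[snp, "tag_ref"], info.loc[snp, "tag_alt"]
        hit = by_pair.get(tuple(sorted((ta, tb))))
        if hit is None:
            continue
        pname, panel_ref = hit
        keep.append(k)
        names.append(pname)
        flips.append(ta != panel_ref)
    codes = called.codes[:, keep].copy()
    for col, flip in enumerate(flips):
        if flip:
            obs = codes[:, col] != MISSING
            codes[obs, col] = 2 - codes[obs, col]
    return GenotypeMatrix(codes=codes, sample_ids=called.sample_ids, marker_names=names)
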