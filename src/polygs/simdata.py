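"""Synthetic populations, phenotypes, progeny trials and GBS read sets.

This module generates data with the statistical structure the downstream
analysis assumes: two outbred reference populations of autotetraploid
genotypes scored at biallelic GBS markers, additive polygenic phenotypes with
a target narrow-sense heritability, replicated half-sib progeny trials, and
barcoded single-end GBS reads built from 64-bp tag pairs.

Genotypes are coded {0, 1, 2} on a pseudo-diploid scale.  In
``tetraploid-collapsed`` mode the generator first draws true tetraploid
dosages 0-4 from Binomial(4, p) (autotetraploid Hardy-Weinberg) and then
collapses the three heterozygous classes {1, 2, 3} to code 1, mirroring how
autotetraploid heterozygotes (Aaaa, AAaa, AAAa) are scored as diploid Aa in
reference-free GBS calling.  The uncollapsed dosage is retained internally so
that simulated read sets can allocate reads by the true allele fraction.

Markers are exchangeable (no linkage map) unless ``n_blocks`` > 1, in which
case markers within a block are correlated through a shared latent founder
gradient — enough LD structure for imputation methods that exploit
marker-marker correlation to beat the per-marker mean.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # integer missing code inside genotype matrices

_BASES = np.array(list("ACGT"))

__all__ = [
    "MISSING",
    "PopulationSpec",
    "TruePolygenicModel",
    "GenotypeMatrix",
    "simulate_population",
    "simulate_two_populations",
    "simulate_progeny_trial",
    "mask_missing",
    "make_tag_panel",
    "simulate_tag_reads",
]


class SimulationError(ValueError):
    """Invalid simulation specification."""


def derive_seed(master: int, label: str) -> int:
    """Derive a stage seed < 2**31 from a master seed and a stage label."""
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class PopulationSpec:
    """Conditions under which one reference population is simulated.

    Parameters
    ----------
    n_individuals, n_markers, n_qtl : int
        Population size, marker-panel size, and number of causal markers.
    h2 : float
        Target narrow-sense heritability of the simulated phenotype, in [0, 1].
    allele_freq_law : callable (rng, size) -> array, optional
        Founder allele-frequency distribution over (0, 1); default U(0.05, 0.95).
    ploidy_mode : {"diploid", "tetraploid-collapsed"}
        How dosages are drawn and coded (see module docstring).
    n_blocks : int
        Number of correlated marker blocks; 1 means exchangeable markers.
    seed : int
        Seed; identical seeds give bit-identical output.
    """

    n_individuals: int
    n_markers: int
    n_qtl: int = 50
    h2: float = 0.2
    allele_freq_law: Callable[[np.random.Generator, int], np.ndarray] | None = None
    ploidy_mode: str = "tetraploid-collapsed"
    n_blocks: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_markers < 1:
            raise SimulationError("n_individuals and n_markers must be positive")
        if self.n_qtl > self.n_markers:
            raise SimulationError(
                f"n_qtl ({self.n_qtl}) exceeds n_markers ({self.n_markers})"
            )
        if not 0.0 <= self.h2 <= 1.0:
            raise SimulationError(f"h2 must lie in [0, 1], got {self.h2}")
        if self.ploidy_mode not in ("diploid", "tetraploid-collapsed"):
            raise SimulationError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        if self.n_blocks < 1:
            raise SimulationError("n_blocks must be >= 1")


@dataclass
class TruePolygenicModel:
    """Ground truth behind a simulated phenotype vector."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    breeding_values: np.ndarray
    residual_sd: float

    def genetic_values(self, codes: np.ndarray) -> np.ndarray:
        """Additive genetic value of arbitrary genotypes on this architecture."""
        return codes[:, self.qtl_indices] @ self.qtl_effects


@dataclass
class GenotypeMatrix:
    """Individuals x markers pseudo-diploid genotype matrix.

    ``codes`` holds {0, 1, 2, MISSING}.  Marker metadata (alleles, flanking
    tags, chromosome/position — "N" with a pseudo-position when unaligned)
    lives in ``marker_info`` indexed like ``marker_names``.
    """

    codes: np.ndarray
    sample_ids: list[str]
    marker_names: list[str]
    marker_info: pd.DataFrame | None = None
    dosages: np.ndarray | None = None  # true tetraploid dosages, when simulated

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.sample_ids), len(self.marker_names)):
            raise ValueError("codes shape does not match sample/marker labels")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing entries."""
        return (self.codes == MISSING).mean(axis=0)

    def select_markers(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            codes=self.codes[:, idx],
            sample_ids=list(self.sample_ids),
            marker_names=[self.marker_names[i] for i in idx],
            marker_info=None if self.marker_info is None else self.marker_info.iloc[idx],
            dosages=None if self.dosages is None else self.dosages[:, idx],
        )

    def select_individuals(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            codes=self.codes[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            marker_names=list(self.marker_names),
            marker_info=self.marker_info,
            dosages=None if self.dosages is None else self.dosages[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, index=self.sample_ids, columns=self.marker_names)
        return df.where(df != MISSING, other=pd.NA)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            codes=self.codes.copy(),
            sample_ids=list(self.sample_ids),
            marker_names=list(self.marker_names),
            marker_info=None if self.marker_info is None else self.marker_info.copy(),
            dosages=None if self.dosages is None else self.dosages.copy(),
        )


def _default_freq_law(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.05, 0.95, size=size)


def _draw_genotypes(
    rng: np.random.Generator, spec: PopulationSpec, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw (codes, dosages) for one population given marker allele freqs."""
    n, m = spec.n_individuals, spec.n_markers
    ploidy = 4 if spec.ploidy_mode == "tetraploid-collapsed" else 2
    if spec.n_blocks > 1:
        # Haplotype blocks: markers in a block mostly copy a latent block
        # dosage pattern (drawn at the block's founder frequency); each
        # marker deviates independently with probability 1 - rho, emulating
        # recombination/mutation.  Within-block LD is ~rho, so the effective
        # number of independent loci is close to n_blocks.
        rho = 0.9
        block_of = np.arange(m) % spec.n_blocks
        block_freq = freqs[: spec.n_blocks]
        latent = rng.binomial(ploidy, block_freq[None, :], size=(n, spec.n_blocks))
        own = rng.binomial(ploidy, freqs[None, :], size=(n, m))
        copy = rng.uniform(size=(n, m)) < rho
        dosages = np.where(copy, latent[:, block_of], own)
    else:
        dosages = rng.binomial(ploidy, np.broadcast_to(freqs, (n, m)))
    if spec.ploidy_mode == "tetraploid-collapsed":
        codes = np.where(dosages == 0, 0, np.where(dosages == 4, 2, 1))
        return codes.astype(np.int8), dosages.astype(np.int8)
    return dosages.astype(np.int8), None


def _attach_phenotype(
    rng: np.random.Generator, spec: PopulationSpec, codes: np.ndarray
) -> tuple[TruePolygenicModel, np.ndarray]:
    qtl_idx = rng.choice(spec.n_markers, size=spec.n_qtl, replace=False)
    effects = rng.normal(size=spec.n_qtl)
    bv = codes[:, qtl_idx].astype(float) @ effects
    var_g = float(np.var(bv))
    if spec.h2 >= 1.0:
        resid_sd = 0.0
    elif spec.h2 <= 0.0:
        # pure-noise limit: phenotype carries no genetic signal at all
        bv_for_pheno = np.zeros_like(bv)
        resid_sd = 1.0
        y = rng.normal(scale=resid_sd, size=len(bv))
        return TruePolygenicModel(qtl_idx, effects, bv, resid_sd), y
    else:
        resid_sd = float(np.sqrt(var_g * (1 - spec.h2) / spec.h2)) if var_g > 0 else 1.0
    y = bv + rng.normal(scale=resid_sd, size=len(bv)) if resid_sd > 0 else bv.copy()
    return TruePolygenicModel(qtl_idx, effects, bv, resid_sd), y


def simulate_population(
    spec: PopulationSpec, prefix: str = "G"
) -> tuple[GenotypeMatrix, TruePolygenicModel, np.ndarray]:
    """Simulate one reference population.

    Returns the genotype matrix, the ground-truth polygenic model, and the
    phenotype vector (breeding value plus Gaussian noise scaled so that the
    expected narrow-sense heritability equals ``spec.h2``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    law = spec.allele_freq_law or _default_freq_law
    freqs = np.asarray(law(rng, spec.n_markers), dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise SimulationError("allele frequencies must lie strictly in (0, 1)")
    codes, dosages = _draw_genotypes(rng, spec, freqs)
    model, y = _attach_phenotype(rng, spec, codes)
    G = GenotypeMatrix(
        codes=codes,
        sample_ids=[f"{prefix}{i:04d}" for i in range(spec.n_individuals)],
        marker_names=[f"M{j:05d}" for j in range(spec.n_markers)],
        dosages=dosages,
    )
    return G, model, y


def simulate_two_populations(
    spec_a: PopulationSpec,
    spec_b: PopulationSpec,
    shared_qtl_fraction: float = 1.0,
    freq_divergence: float = 0.0,
    seed: int = 0,
) -> tuple[
    tuple[GenotypeMatrix, TruePolygenicModel, np.ndarray],
    tuple[GenotypeMatrix, TruePolygenicModel, np.ndarray],
]:
    """Simulate two populations sharing one marker panel.

    A fraction ``shared_qtl_fraction`` of QTL keep identical positions and
    effects across populations; the rest are redrawn independently in
    population B.  Founder allele frequencies of B are perturbed by a Gaussian
    kick of scale ``freq_divergence`` (clipped to (0.02, 0.98)), emulating two
    genetically contrasting germplasm pools genotyped on the same markers.
    """
    if not 0.0 <= shared_qtl_fraction <= 1.0:
        raise SimulationError("shared_qtl_fraction must lie in [0, 1]")
    if spec_a.n_markers != spec_b.n_markers:
        raise SimulationError("both populations must share the marker panel")
    rng = np.random.default_rng(seed)
    law = spec_a.allele_freq_law or _default_freq_law
    freqs_a = np.asarray(law(rng, spec_a.n_markers), dtype=float)
    freqs_b = np.clip(
        freqs_a + rng.normal(scale=freq_divergence, size=freqs_a.shape)
        if freq_divergence > 0
        else freqs_a.copy(),
        0.02,
        0.98,
    )

    codes_a, dos_a = _draw_genotypes(rng, spec_a, freqs_a)
    codes_b, dos_b = _draw_genotypes(rng, spec_b, freqs_b)

    m = spec_a.n_markers
    qtl_a = rng.choice(m, size=spec_a.n_qtl, replace=False)
    eff_a = rng.normal(size=spec_a.n_qtl)
    n_shared = int(round(shared_qtl_fraction * spec_b.n_qtl))
    shared = qtl_a[:n_shared]
    # private QTL avoid population A's architecture entirely, so the shared
    # fraction is exactly the fraction of identical (position, effect) pairs
    pool = np.setdiff1d(np.arange(m), qtl_a)
    n_private = spec_b.n_qtl - n_shared
    if len(pool) < n_private:
        pool = np.setdiff1d(np.arange(m), shared)
    private = rng.choice(pool, size=n_private, replace=False)
    qtl_b = np.concatenate([shared, private])
    eff_b = np.concatenate([eff_a[:n_shared], rng.normal(size=spec_b.n_qtl - n_shared)])

    out = []
    for codes, dos, qtl, eff, spec, prefix in (
        (codes_a, dos_a, qtl_a, eff_a, spec_a, "A"),
        (codes_b, dos_b, qtl_b, eff_b, spec_b, "B"),
    ):
        bv = codes[:, qtl].astype(float) @ eff
        var_g = float(np.var(bv))
        if spec.h2 >= 1.0:
            resid_sd = 0.0
        elif spec.h2 <= 0.0 or var_g == 0:
            resid_sd = 1.0
            bv = np.zeros_like(bv) if spec.h2 <= 0.0 else bv
        else:
            resid_sd = float(np.sqrt(var_g * (1 - spec.h2) / spec.h2))
        y = bv + rng.normal(scale=resid_sd, size=len(bv)) if resid_sd > 0 else bv.copy()
        G = GenotypeMatrix(
            codes=codes,
            sample_ids=[f"{prefix}{i:04d}" for i in range(spec.n_individuals)],
            marker_names=[f"M{j:05d}" for j in range(m)],
            dosages=dos,
        )
        out.append((G, TruePolygenicModel(qtl, eff, bv, resid_sd), y))
    return out[0], out[1]


def simulate_progeny_trial(
    breeding_values: np.ndarray,
    r: int = 2,
    s2_hs: float = 1.0,
    s2_e: float = 2.0,
    seed: int = 0,
    grand_mean: float = 10.0,
) -> pd.DataFrame:
    """Simulate a replicated half-sib progeny trial (complete blocks).

    Each parent contributes one half-sib progeny plot per replication.  Plot
    value = grand mean + block effect + progeny effect + plot error.  The
    progeny effect is half the parent breeding value plus a Mendelian-sampling
    term, jointly rescaled so that the between-progeny variance equals
    ``s2_hs``; plot errors are N(0, s2_e).

    Returns a tidy trial table with columns ``progeny_id``, ``replication_id``
    and ``plot_value``.
    """
    if r < 1:
        raise SimulationError("at least one replication is required")
    if s2_hs < 0 or s2_e < 0:
        raise SimulationError("variance components must be non-negative")
    bv = np.asarray(breeding_values, dtype=float)
    n = len(bv)
    rng = np.random.default_rng(seed)
    transmitted = 0.5 * (bv - bv.mean())
    mendelian = rng.normal(scale=np.std(transmitted) if n > 1 else 1.0, size=n)
    raw = transmitted + mendelian
    sd_raw = np.std(raw)
    progeny_eff = raw * (np.sqrt(s2_hs) / sd_raw) if sd_raw > 0 else np.zeros(n)
    block_eff = rng.normal(scale=0.5, size=r)
    rows = []
    for b in range(r):
        errors = rng.normal(scale=np.sqrt(s2_e), size=n) if s2_e > 0 else np.zeros(n)
        vals = grand_mean + block_eff[b] + progeny_eff + errors
        rows.append(
            pd.DataFrame(
                {
                    "progeny_id": [f"P{i:04d}" for i in range(n)],
                    "replication_id": b + 1,
                    "plot_value": vals,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def mask_missing(
    G: GenotypeMatrix,
    marker_rate_law: Callable[[np.random.Generator, int], np.ndarray] | float | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Set entries missing with per-marker rates drawn from ``marker_rate_law``.

    The default law is Beta(1.2, 3.0) — a right-skewed per-marker missing-rate
    distribution so that threshold filtering is non-degenerate.  A float is
    treated as a point mass.  Observed entries are never altered.
    """
    if np.any(G.codes == MISSING):
        raise SimulationError("input matrix already contains missing values")
    rng = np.random.default_rng(seed)
    m = G.n_markers
    if marker_rate_law is None:
        rates = rng.beta(1.2, 3.0, size=m)
    elif callable(marker_rate_law):
        rates = np.asarray(marker_rate_law(rng, m), dtype=float)
    else:
        rates = np.full(m, float(marker_rate_law))
    if np.any((rates < 0) | (rates > 1)):
        raise SimulationError("missing rates must lie in [0, 1]")
    mask = rng.uniform(size=G.codes.shape) < rates[None, :]
    out = G.copy()
    out.codes = np.where(mask, MISSING, out.codes).astype(out.codes.dtype)
    return out


# ---------------------------------------------------------------------------
# GBS read simulation


def _random_tag(rng: np.random.Generator, remnant: str) -> str:
    body = "".join(rng.choice(_BASES, size=64 - len(remnant)))
    return remnant + body


def make_tag_panel(
    n_markers: int, seed: int = 0, cutsite_remnant: str = "CAGC"
) -> pd.DataFrame:
    """Build a panel of 64-bp tag pairs, one pair per marker.

    Each pair differs at exactly one position downstream of the cut-site
    remnant; the pair (reference tag, alternate tag) defines the biallelic
    marker exactly as reference-free tag-pair calling expects.
    """
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records = []
    while len(records) < n_markers:
        ref = _random_tag(rng, cutsite_remnant)
        pos = int(rng.integers(len(cutsite_remnant), 64))
        alt_base = rng.choice([b for b in "ACGT" if b != ref[pos]])
        alt = ref[:pos] + alt_base + ref[pos + 1 :]
        if ref in seen or alt in seen:
            continue
        seen.update((ref, alt))
        records.append({"marker": f"M{len(records):05d}", "tag_ref": ref, "tag_alt": alt, "snp_pos": pos})
    return pd.DataFrame(records).set_index("marker")


def _validate_panel(panel: pd.DataFrame) -> None:
    for _, row in panel.iterrows():
        a, b = row["tag_ref"], row["tag_alt"]
        if len(a) != 64 or len(b) != 64:
            raise SimulationError("tags must be exactly 64 bp")
        if sum(x != y for x, y in zip(a, b)) != 1:
            raise SimulationError("tag pairs must differ at exactly 1 bp")


def simulate_tag_reads(
    G: GenotypeMatrix,
    panel: pd.DataFrame,
    fastq_path,
    key_path,
    mean_depth: float = 60.0,
    depth_dispersion: float = 5.0,
    error_rate: float = 0.0,
    seed: int = 0,
    barcodes: list[str] | None = None,
) -> None:
    """Write barcoded single-end GBS reads and the matching key table.

    Per individual x marker the read count is negative binomial with mean
    ``mean_depth`` (Poisson when ``depth_dispersion`` is None/inf); reads are
    split between the two tags of the pair binomially with allele fraction
    q/4 from the true tetraploid dosage q (or code/2 for diploid input).
    Reads are barcode + tag (the cut-site remnant is the first bases of the
    tag, as on real GBS reads); sequencing errors flip bases uniformly at
    ``error_rate``.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    _validate_panel(panel)
    if len(panel) != G.n_markers:
        raise SimulationError("panel size must match the genotype matrix")
    rng = np.random.default_rng(seed)
    n = G.n_individuals
    if barcodes is None:
        barcodes = _default_barcodes(n, rng)
    if len(set(barcodes)) != n:
        raise SimulationError("barcodes must be unique")

    if G.dosages is not None:
        alt_frac = G.dosages / 4.0
    else:
        alt_frac = G.codes / 2.0

    if mean_depth < 0:
        raise SimulationError("mean depth must be non-negative")
    if mean_depth == 0:
        depths = np.zeros((n, G.n_markers), dtype=int)
    elif depth_dispersion is None or not np.isfinite(depth_dispersion):
        depths = rng.poisson(mean_depth, size=(n, G.n_markers))
    else:
        k = depth_dispersion
        p = k / (k + mean_depth)
        depths = rng.negative_binomial(k, p, size=(n, G.n_markers))

    tag_ref = panel["tag_ref"].to_numpy()
    tag_alt = panel["tag_alt"].to_numpy()
    records = []
    rid = 0
    for i in range(n):
        bc = barcodes[i]
        for j in range(G.n_markers):
            d = int(depths[i, j])
            if d == 0:
                continue
            n_alt = int(rng.binomial(d, alt_frac[i, j]))
            for tag, cnt in ((tag_ref[j], d - n_alt), (tag_alt[j], n_alt)):
                for _ in range(cnt):
                    seq = bc + tag
                    if error_rate > 0:
                        seq = _mutate(rng, seq, error_rate)
                    rec = SeqRecord(Seq(seq), id=f"read{rid}", description="")
                    rec.letter_annotations["phred_quality"] = [40] * len(seq)
                    records.append(rec)
                    rid += 1
    with _maybe_gz(fastq_path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")
    key = pd.DataFrame(
        {"flowcell_lane": "SIMLANE1", "barcode": barcodes, "sample_id": G.sample_ids}
    )
    key.to_csv(key_path, sep="\t", index=False)


def _default_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    # 4-8 bp variable-length barcodes like real GBS keys, prefix-free so that
    # greedy longest-match demultiplexing is unambiguous
    out: set[str] = set()
    length = 6
    while len(out) < n:
        cand = "".join(rng.choice(_BASES, size=length))
        if any(cand.startswith(b) or b.startswith(cand) for b in out):
            continue
        out.add(cand)
    return sorted(out)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.uniform(size=len(arr)) < rate)[0]
    for h in hits:
        arr[h] = rng.choice([b for b in "ACGT" if b != arr[h]])
    return "".join(arr)


def _maybe_gz(path, mode: str):
    import gzip

    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
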