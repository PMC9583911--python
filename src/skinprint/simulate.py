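"""Synthetic skin-metagenome cohorts with planted individual-specific variants.

The simulator emulates the structure the fingerprinting method exploits: a
cohort of individuals who all carry the same background species and the same
dominant resident species, except that each individual's resident strain bears
a small number of private variants (SNVs and 1-bp indels) stable across body
sites and timepoints.  Genomes are i.i.d. random sequence — no repeat
structure — so k-mer uniqueness is analysable and the ground truth (each
individual's private canonical k-mers) is recoverable by exact set difference
between haplotypes.  Reads are uniform single-end (optionally paired) with a
substitution-only error model and log-normal depth variation across samples.

Everything is deterministic given the spec's seed; per-sample streams are
seeded independently so the output does not depend on generation order.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import CohortManifest, SampleRecord
from .seqcodes import window_codes, encode_bases, codes_to_kmers

# skin body sites with their physiological stratum (sebaceous / moist / dry)
SITE_TYPES = {
    "Gb": "sebaceous",
    "Ba": "sebaceous",
    "Oc": "sebaceous",
    "Ac": "moist",
    "Pc": "moist",
    "Id": "moist",
    "Vf": "dry",
    "Hp": "dry",
}
_SITE_ORDER = ["Gb", "Ac", "Vf", "Ba", "Pc", "Hp", "Oc", "Id"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Variant:
    position: int      # 0-based on the resident reference
    kind: str          # "snv" | "ins" | "del"
    ref: str
    alt: str


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    n_individuals: int = 6
    n_body_sites: int = 4
    n_timepoints: int = 2
    resident_length: int = 50_000
    resident_abundance: float = 1 / 3
    backgrounds: tuple[tuple[int, float], ...] = ((30_000, 1 / 3), (30_000, 1 / 3))
    n_private_snvs: int = 5
    n_private_indels: int = 1
    read_length: int = 101
    mean_depth: float = 20.0
    depth_sigma: float = 0.0           # log-normal spread of per-sample depth
    error_rate: float = 0.0            # per-base substitution probability
    paired: bool = False
    insert_size: int = 300
    k: int = 31
    seed: int = 0
    # individuals whose private variants are absent at the listed timepoints
    variant_dropout: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.resident_abundance + sum(a for _, a in self.backgrounds)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genome abundances must sum to 1; got {total}")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_body_sites > len(_SITE_ORDER):
            raise ValueError(f"at most {len(_SITE_ORDER)} body sites supported")

    @property
    def sites(self) -> list[str]:
        return _SITE_ORDER[: self.n_body_sites]

    @property
    def timepoints(self) -> list[str]:
        return [f"T{i+1}" for i in range(self.n_timepoints)]

    @property
    def individuals(self) -> list[str]:
        return [f"HV{i+1:02d}" for i in range(self.n_individuals)]


@dataclass
class CohortTruth:
    """Planted variants and the private canonical k-mers they create."""

    k: int
    variants: dict[str, list[Variant]]
    kmers: dict[str, frozenset[str]]

    def to_tsv(self, variants_path: str | Path, kmers_path: str | Path) -> None:
        with open(variants_path, "w") as fh:
            fh.write("individual_id\tposition\tkind\tref\talt\n")
            for ind in sorted(self.variants):
                for v in self.variants[ind]:
                    fh.write(f"{ind}\t{v.position}\t{v.kind}\t{v.ref}\t{v.alt}\n")
        with open(kmers_path, "w") as fh:
            fh.write("individual_id\tkmer\n")
            for ind in sorted(self.kmers):
                for km in sorted(self.kmers[ind]):
                    fh.write(f"{ind}\t{km}\n")


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _place_positions(
    rng: np.random.Generator,
    n: int,
    genome_length: int,
    min_separation: int,
    margin: int,
    excluded: list[int] | None = None,
) -> list[int]:
    """Sample n positions pairwise >= min_separation apart, away from ends."""
    chosen: list[int] = []
    blocked = list(excluded or [])
    for _ in range(20_000):
        if len(chosen) == n:
            break
        pos = int(rng.integers(margin, genome_length - margin))
        if all(abs(pos - q) >= min_separation for q in chosen + blocked):
            chosen.append(pos)
    if len(chosen) < n:
        raise ValueError(
            "could not place non-overlapping variants; use a longer resident genome"
        )
    return chosen


def _min_separation(spec: CohortSpec) -> int:
    # planted loci are independent markers: far enough apart that no read can
    # span two loci and no two loci can merge into one contig whose interior
    # would admit full-length reads from other donors
    return max(3 * spec.k, 3 * spec.read_length)


def _apply_variants(reference: str, variants: list[Variant]) -> str:
    seq = reference
    for v in sorted(variants, key=lambda v: -v.position):
        if v.kind == "snv":
            seq = seq[: v.position] + v.alt + seq[v.position + 1 :]
        elif v.kind == "ins":
            seq = seq[: v.position] + v.alt + seq[v.position :]
        elif v.kind == "del":
            seq = seq[: v.position] + seq[v.position + 1 :]
        else:  # pragma: no cover
            raise ValueError(v.kind)
    return seq


def _draw_variants(
    rng: np.random.Generator, reference: str, positions: list[int], n_snvs: int
) -> list[Variant]:
    variants = []
    for i, pos in enumerate(positions):
        ref_base = reference[pos]
        if i < n_snvs:
            alt = "ACGT"[("ACGT".index(ref_base) + int(rng.integers(1, 4))) % 4]
            variants.append(Variant(pos, "snv", ref_base, alt))
        elif rng.random() < 0.5:
            variants.append(Variant(pos, "ins", "-", "ACGT"[int(rng.integers(0, 4))]))
        else:
            variants.append(Variant(pos, "del", ref_base, "-"))
    return sorted(variants, key=lambda v: v.position)


def _genome_codes(seq: str, k: int) -> np.ndarray:
    codes, valid = window_codes(encode_bases(seq), k)
    return np.unique(codes[valid])


@dataclass
class _CohortGenomes:
    reference: str
    backgrounds: list[str]
    variants: dict[str, list[Variant]]
    haplotypes: dict[str, str]
    variant_positions: list[int]


def _cohort_genomes(spec: CohortSpec) -> _CohortGenomes:
    """Genomes, variants and haplotypes as a pure function of the spec."""
    rng = np.random.default_rng([spec.seed, 0])
    reference = _random_genome(rng, spec.resident_length)
    backgrounds = [_random_genome(rng, ln) for ln, _ in spec.backgrounds]
    n_var = spec.n_private_snvs + spec.n_private_indels
    positions = _place_positions(
        rng,
        n=n_var * spec.n_individuals,
        genome_length=spec.resident_length,
        min_separation=_min_separation(spec),
        margin=2 * spec.k,
    )
    variants: dict[str, list[Variant]] = {}
    haplotypes: dict[str, str] = {}
    for i, ind in enumerate(spec.individuals):
        own = positions[i * n_var : (i + 1) * n_var]
        variants[ind] = _draw_variants(rng, reference, own, spec.n_private_snvs)
        haplotypes[ind] = _apply_variants(reference, variants[ind])
    return _CohortGenomes(reference, backgrounds, variants, haplotypes, positions)


def cohort_truth(spec: CohortSpec) -> CohortTruth:
    """Ground-truth private k-mers by brute k-mer set difference."""
    g = _cohort_genomes(spec)
    k = spec.k
    hap_codes = {ind: _genome_codes(seq, k) for ind, seq in g.haplotypes.items()}
    shared = [_genome_codes(g.reference, k)] + [_genome_codes(b, k) for b in g.backgrounds]
    kmers: dict[str, frozenset[str]] = {}
    for ind in spec.individuals:
        others = shared + [hap_codes[o] for o in spec.individuals if o != ind]
        private = np.setdiff1d(hap_codes[ind], np.unique(np.concatenate(others)))
        kmers[ind] = frozenset(codes_to_kmers(private, k))
    return CohortTruth(k=k, variants=g.variants, kmers=kmers)


def _simulate_reads(
    rng: np.random.Generator,
    genomes: list[tuple[str, float]],
    read_length: int,
    depth: float,
    error_rate: float,
) -> list[str]:
    """Uniform reads over the genomes; coverage of genome g is depth×(a_g/ā)."""
    mean_ab = float(np.mean([a for _, a in genomes]))
    chunks: list[np.ndarray] = []
    for seq, ab in genomes:
        cov = depth * ab / mean_ab
        n = int(round(cov * len(seq) / read_length))
        if n == 0:
            continue
        arr = encode_bases(seq)
        starts = rng.integers(0, len(seq) - read_length + 1, n)
        mat = arr[starts[:, None] + np.arange(read_length)]
        rc = rng.random(n) < 0.5
        mat[rc] = (mat[rc, ::-1] ^ 3).astype(np.uint8)
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4
        chunks.append(mat)
    if not chunks:
        return []
    all_mat = np.concatenate(chunks)
    # shuffle so genome origin is not positional
    all_mat = all_mat[rng.permutation(all_mat.shape[0])]
    flat = _BASES[all_mat].tobytes().decode("ascii")
    return [flat[i * read_length : (i + 1) * read_length] for i in range(all_mat.shape[0])]


def _write_fastq_gz(path: Path, sample_id: str, reads: list[str], read_length: int) -> None:
    qual = "I" * read_length
    text = "".join(
        f"@{sample_id}_r{i}\n{seq}\n+\n{qual[: len(seq)]}\n" for i, seq in enumerate(reads)
    )
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", compresslevel=1, mtime=0) as gz:
            with io.TextIOWrapper(gz) as fh:
                fh.write(text)


def _sample_depth(spec: CohortSpec, rng: np.random.Generator) -> float:
    if spec.depth_sigma == 0:
        return spec.mean_depth
    # log-normal with unit mean so the cohort average stays at mean_depth
    mult = rng.lognormal(-spec.depth_sigma**2 / 2, spec.depth_sigma)
    return spec.mean_depth * mult


def simulate_cohort(spec: CohortSpec, out_dir: str | Path) -> tuple[CohortManifest, CohortTruth]:
    """Write per-sample FASTQ, a manifest TSV, genomes and ground truth.

    Returns the manifest (with cached read counts) and the cohort truth.
    """
    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    g = _cohort_genomes(spec)
    truth = cohort_truth(spec)
    samples = []
    sample_index = 0
    for ind in spec.individuals:
        for site in spec.sites:
            for tp in spec.timepoints:
                sample_index += 1
                sid = f"{ind}_{site}_{tp}"
                rng = np.random.default_rng([spec.seed, 1, sample_index])
                dropped = tp in spec.variant_dropout.get(ind, ())
                resident = g.reference if dropped else g.haplotypes[ind]
                genomes = [(resident, spec.resident_abundance)] + [
                    (bg, ab) for bg, (_, ab) in zip(g.backgrounds, spec.backgrounds)
                ]
                depth = _sample_depth(spec, rng)
                reads = _simulate_reads(
                    rng, genomes, spec.read_length, depth, spec.error_rate
                )
                paths: tuple[str, ...]
                if spec.paired:
                    paths = _write_paired(out, sid, reads, spec, rng)
                else:
                    p = out / "reads" / f"{sid}.fastq.gz"
                    _write_fastq_gz(p, sid, reads, spec.read_length)
                    paths = (str(p),)
                samples.append(
                    SampleRecord(
                        sample_id=sid,
                        individual_id=ind,
                        body_site=site,
                        timepoint=tp,
                        read_paths=paths,
                        n_reads=len(reads),
                    )
                )
    manifest = CohortManifest(samples=samples)
    manifest.to_tsv(out / "manifest.tsv")
    truth.to_tsv(out / "truth_variants.tsv", out / "truth_kmers.tsv")
    with open(out / "genomes.fasta", "w") as fh:
        fh.write(f">resident_reference\n{g.reference}\n")
        for i, bg in enumerate(g.backgrounds):
            fh.write(f">background_{i+1}\n{bg}\n")
        for ind in spec.individuals:
            fh.write(f">resident_{ind}\n{g.haplotypes[ind]}\n")
    return manifest, truth


def _write_paired(
    out: Path, sid: str, reads: list[str], spec: CohortSpec, rng: np.random.Generator
) -> tuple[str, str]:
    # mate 1 is the simulated read; mate 2 a second read drawn from the same
    # stream — pairing carries no extra information for any algorithm here
    half = len(reads) // 2
    p1 = out / "reads" / f"{sid}_1.fastq.gz"
    p2 = out / "reads" / f"{sid}_2.fastq.gz"
    _write_fastq_gz(p1, sid + "/1", reads[:half], spec.read_length)
    _write_fastq_gz(p2, sid + "/2", reads[half : 2 * half], spec.read_length)
    return (str(p1), str(p2))


def make_outgroup_sample(
    spec: CohortSpec, seed: int, out_dir: str | Path, sample_id: str = "OUTGROUP"
) -> tuple[str, frozenset[str]]:
    """One sample from a donor outside the cohort, sharing the backgrounds.

    The outgroup haplotype carries its own private variants, placed away from
    every cohort variant so its k-mers never collide with cohort truth k-mers.
    Returns the FASTQ path and the outgroup's own private k-mer set.
    """
    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    g = _cohort_genomes(spec)
    rng = np.random.default_rng([spec.seed, 2, seed])
    n_var = spec.n_private_snvs + spec.n_private_indels
    positions = _place_positions(
        rng,
        n=n_var,
        genome_length=spec.resident_length,
        min_separation=_min_separation(spec),
        margin=2 * spec.k,
        excluded=g.variant_positions,
    )
    variants = _draw_variants(rng, g.reference, positions, spec.n_private_snvs)
    haplotype = _apply_variants(g.reference, variants)
    genomes = [(haplotype, spec.resident_abundance)] + [
        (bg, ab) for bg, (_, ab) in zip(g.backgrounds, spec.backgrounds)
    ]
    depth = _sample_depth(spec, rng)
    reads = _simulate_reads(rng, genomes, spec.read_length, depth, spec.error_rate)
    path = out / "reads" / f"{sample_id}.fastq.gz"
    _write_fastq_gz(path, sample_id, reads, spec.read_length)
    hap = _genome_codes(haplotype, spec.k)
    shared = [_genome_codes(g.reference, spec.k)] + [
        _genome_codes(b, spec.k) for b in g.backgrounds
    ]
    private = np.setdiff1d(hap, np.unique(np.concatenate(shared)))
    return str(path), frozenset(codes_to_kmers(private, spec.k))
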