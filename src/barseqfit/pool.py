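"""Synthetic pooled-competition experiments with known ground truth.

Emulates a bar-seq fitness screen: a pool of uniquely barcoded yeast strains
is propagated in a nutrient-limited chemostat for ~20 generations, sampled
every three generations, and the abundance of each strain is read out by
sequencing its 20-bp molecular barcode.  Population sizes in such experiments
(~1e9 cells) make drift negligible, so propagation is modeled as
deterministic discrete-generation relative growth; stochasticity enters only
through the finite sequencing depth (a multinomial draw per sample).
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrainSpec",
    "CompetitionDesign",
    "DfeMixture",
    "TruthTable",
    "ReadLayout",
    "DEFAULT_LAYOUT",
    "COLLECTIONS",
    "propagate_frequencies",
    "sample_counts",
    "generate_reads",
    "build_pool",
    "simulate_counts",
    "write_fastq",
]

COLLECTIONS = (
    "haploid_deletion",
    "het_diploid_deletion",
    "low_copy_plasmid",
    "high_copy_plasmid",
    "control",
)

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass(frozen=True)
class StrainSpec:
    """One barcoded strain: identity, 20-mer barcode, and true fitness.

    ``true_fitness`` is the per-generation selection coefficient *s* relative
    to the reference (s = 0 is neutral, s = 0.10 a 10% per-generation
    advantage).  Must exceed -1 (s = -1 would be instant death).
    """

    strain_id: str
    barcode: str
    gene: str
    collection: str
    true_fitness: float

    def __post_init__(self) -> None:
        if len(self.barcode) != 20:
            raise ValueError(
                f"strain {self.strain_id!r}: barcode must be 20 bases, "
                f"got {len(self.barcode)}"
            )
        if set(self.barcode) - set("ACGT"):
            raise ValueError(
                f"strain {self.strain_id!r}: barcode has characters outside ACGT"
            )
        if self.collection not in COLLECTIONS:
            raise ValueError(
                f"strain {self.strain_id!r}: unknown collection {self.collection!r}"
            )
        if not self.true_fitness > -1:
            raise ValueError(
                f"strain {self.strain_id!r}: true_fitness must be > -1, "
                f"got {self.true_fitness}"
            )


@dataclasses.dataclass(frozen=True)
class ReadLayout:
    """Fixed layout of a single 36-base read.

    ``[6-mer sample tag][constant spacer][20-mer strain barcode]``.  The
    spacer stands in for the constant priming sequence between the multiplex
    tag and the barcode; its content is arbitrary but fixed so that the
    barcode sits at a known offset.
    """

    tag_length: int = 6
    spacer: str = "CGTACGCTGC"
    barcode_length: int = 20

    @property
    def barcode_offset(self) -> int:
        return self.tag_length + len(self.spacer)

    @property
    def read_length(self) -> int:
        return self.barcode_offset + self.barcode_length


DEFAULT_LAYOUT = ReadLayout()


@dataclasses.dataclass(frozen=True)
class CompetitionDesign:
    """Design of one pooled-competition screen.

    Defaults mirror the study conditions: sampling every ~3 generations over
    20 generations of continuous culture, two replicate screens, and a mean
    sequencing depth of 462 reads per strain per sample.
    """

    condition: str = "glucose"
    timepoints: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18, 20)
    replicates: int = 2
    depth_per_strain: float = 462.0
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(self.timepoints)
        if not tps or tps[0] != 0:
            raise ValueError("timepoints must start at generation 0")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.depth_per_strain < 0:
            raise ValueError("depth_per_strain must be >= 0")

    def total_depth(self, n_strains: int) -> int:
        return int(round(self.depth_per_strain * n_strains))

    def samples(self) -> Iterator[tuple[str, int, int]]:
        """Yield (condition, replicate, timepoint) for every sample."""
        for rep in range(1, self.replicates + 1):
            for t in self.timepoints:
                yield (self.condition, rep, t)


@dataclasses.dataclass(frozen=True)
class DfeMixture:
    """Mixture describing the distribution of true fitness effects.

    A point mass of neutral strains plus uniform beneficial and deleterious
    components.  The default (90% neutral, 5% beneficial ~ U(0, 0.4),
    5% deleterious ~ U(-0.3, 0)) produces a mostly-neutral pool with a
    minority of selected strains; it is a testing choice, configurable.
    """

    neutral: float = 0.90
    beneficial: float = 0.05
    deleterious: float = 0.05
    beneficial_range: tuple[float, float] = (0.0, 0.4)
    deleterious_range: tuple[float, float] = (-0.3, 0.0)

    def __post_init__(self) -> None:
        w = (self.neutral, self.beneficial, self.deleterious)
        if any(x < 0 for x in w) or not math.isclose(sum(w), 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights must be >= 0 and sum to 1, got {w}")
        if self.deleterious_range[0] <= -1:
            raise ValueError("deleterious fitness must stay > -1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(3, size=n, p=[self.neutral, self.beneficial, self.deleterious])
        s = np.zeros(n)
        nb = int((comp == 1).sum())
        nd = int((comp == 2).sum())
        s[comp == 1] = rng.uniform(*self.beneficial_range, size=nb)
        s[comp == 2] = rng.uniform(*self.deleterious_range, size=nd)
        return s


@dataclasses.dataclass
class TruthTable:
    """Ground truth of a simulated screen: fitness and frequency trajectories.

    ``frequencies`` maps (condition, replicate, timepoint) -> frequency
    vector aligned with ``strain_ids``.
    """

    strain_ids: list[str]
    true_fitness: np.ndarray
    frequencies: dict[tuple[str, int, int], np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        cols = {
            f"{c}_r{r}_g{t}": v for (c, r, t), v in sorted(self.frequencies.items())
        }
        frame = pd.DataFrame(cols, index=pd.Index(self.strain_ids, name="strain_id"))
        frame.insert(0, "true_fitness", self.true_fitness)
        return frame


def propagate_frequencies(
    f0: np.ndarray, s: np.ndarray, t: int
) -> np.ndarray:
    """Deterministic relative growth: f_i(t) ∝ f_i(0) (1+s_i)^t.

    Returns the renormalized frequency vector after ``t`` generations of
    selection.  Order is preserved; the output sums to 1.
    """
    f0 = np.asarray(f0, dtype=float)
    s = np.asarray(s, dtype=float)
    if f0.shape != s.shape:
        raise ValueError(f"shape mismatch: f0 {f0.shape} vs s {s.shape}")
    if t < 0:
        raise ValueError(f"generations t must be >= 0, got {t}")
    neg = np.flatnonzero(f0 < 0)
    if neg.size:
        raise ValueError(f"negative frequency at index {neg[0]}: {f0[neg[0]]}")
    bad = np.flatnonzero(s <= -1)
    if bad.size:
        raise ValueError(f"fitness at index {bad[0]} is <= -1: {s[bad[0]]}")
    if not math.isclose(f0.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"f0 must sum to 1, sums to {f0.sum()!r}")
    # log-space growth for numerical stability at large t
    logw = f0 * 0.0
    np.log1p(s, out=logw)
    logf = np.where(f0 > 0, np.log(np.where(f0 > 0, f0, 1.0)) + t * logw, -np.inf)
    logf -= logf.max()
    f = np.exp(logf)
    f[f0 == 0] = 0.0
    return f / f.sum()


def sample_counts(
    freqs: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial sequencing draw: ``depth`` reads over strain frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    if (freqs < 0).any():
        raise ValueError("frequencies must be >= 0")
    if not math.isclose(freqs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"frequencies must sum to 1, sum is {freqs.sum()!r}")
    return rng.multinomial(depth, freqs / freqs.sum())


def _random_unique_kmers(n: int, k: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out) + 8, k))
        for row in block:
            kmer = "".join(_BASES[row])
            if kmer not in seen:
                seen.add(kmer)
                out.append(kmer)
                if len(out) == n:
                    break
    return out


def build_pool(
    n_strains: int,
    dfe_spec: DfeMixture | None = None,
    n_control: int = 0,
    seed: int = 0,
    collection: str = "haploid_deletion",
) -> tuple[list[StrainSpec], np.ndarray]:
    """Build a barcoded strain pool with known fitness.

    Returns ``(catalog, true_fitness)`` where the catalog holds
    ``n_strains`` test strains (fitness drawn from ``dfe_spec``) followed by
    ``n_control`` neutral control strains.  Barcodes are unique random
    20-mers; deterministic under a fixed seed.
    """
    if n_strains <= 0:
        raise ValueError("n_strains must be > 0")
    if n_control < 0:
        raise ValueError("n_control must be >= 0")
    dfe_spec = dfe_spec or DfeMixture()
    rng = np.random.default_rng(seed)
    total = n_strains + n_control
    barcodes = _random_unique_kmers(total, 20, rng)
    s = np.concatenate([dfe_spec.sample(n_strains, rng), np.zeros(n_control)])
    catalog = []
    for i in range(total):
        is_ctrl = i >= n_strains
        catalog.append(
            StrainSpec(
                strain_id=f"{'ctrl' if is_ctrl else 'strain'}{i:05d}",
                barcode=barcodes[i],
                gene=f"GENE{i:05d}" if not is_ctrl else f"NEUTRAL{i - n_strains:05d}",
                collection="control" if is_ctrl else collection,
                true_fitness=float(s[i]),
            )
        )
    return catalog, s


def simulate_counts(
    catalog: Sequence[StrainSpec],
    design: CompetitionDesign,
    noise: bool = True,
) -> tuple[pd.DataFrame, TruthTable]:
    """Run the competition in silico and return sequencing counts + truth.

    Counts are a strains × samples table with a MultiIndex column
    ``(condition, replicate, timepoint)``.  With ``noise=False`` the table
    holds exact expected (real-valued) counts ``depth * frequency`` instead
    of multinomial draws — useful for oracle checks, since all randomness of
    the readout lives in the multinomial step.
    """
    ids = [st.strain_id for st in catalog]
    s = np.array([st.true_fitness for st in catalog])
    n = len(catalog)
    f0 = np.full(n, 1.0 / n)  # strains pooled at equal proportions
    depth = design.total_depth(n)
    rng = np.random.default_rng(design.seed)
    freqs: dict[tuple[str, int, int], np.ndarray] = {}
    data: dict[tuple[str, int, int], np.ndarray] = {}
    for cond, rep, t in design.samples():
        f = propagate_frequencies(f0, s, t)
        freqs[(cond, rep, t)] = f
        data[(cond, rep, t)] = (
            sample_counts(f, depth, rng) if noise else depth * f
        )
    counts = pd.DataFrame(data, index=pd.Index(ids, name="strain_id"))
    counts.columns = pd.MultiIndex.from_tuples(
        counts.columns, names=["condition", "replicate", "timepoint"]
    )
    return counts, TruthTable(ids, s, freqs)


def generate_reads(
    counts: Mapping[str, int],
    catalog: Sequence[StrainSpec],
    tag: str,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> Iterator[tuple[str, str, str]]:
    """Yield FASTQ records (title, sequence, quality) for one sample.

    Each strain contributes ``counts[strain_id]`` identical reads laid out as
    tag + spacer + barcode with uniform dummy qualities.
    """
    if len(tag) != layout.tag_length:
        raise ValueError(f"tag must be {layout.tag_length} bases, got {tag!r}")
    by_id = {st.strain_id: st for st in catalog}
    qual = "I" * layout.read_length
    i = 0
    for strain_id, c in counts.items():
        if strain_id not in by_id:
            raise KeyError(f"unknown strain id {strain_id!r} in counts")
        seq = tag + layout.spacer + by_id[strain_id].barcode
        for _ in range(int(c)):
            yield (f"read{i}:{strain_id}", seq, qual)
            i += 1


def make_tag_map(
    design: CompetitionDesign, seed: int | None = None
) -> dict[tuple[str, int, int], str]:
    """Assign a unique 6-mer multiplex tag to every sample of a design."""
    samples = list(design.samples())
    rng = np.random.default_rng(design.seed if seed is None else seed)
    tags = _random_unique_kmers(len(samples), DEFAULT_LAYOUT.tag_length, rng)
    return dict(zip(samples, tags))


def write_fastq(
    records: Iterable[tuple[str, str, str]], path, append: bool = False
) -> int:
    """Write (title, seq, qual) records as 4-line FASTQ; returns n written."""
    n = 0
    with open(path, "a" if append else "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
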