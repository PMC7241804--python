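"""Synthetic junction-count experiments with known ground truth.

The generator emulates the statistical structure the splice-structure test
assumes: a gene expresses a mixture of transcripts, each transcript uses a
fixed subset of the gene's junctions, and the observed junction counts are
reads sampled from that mixture.  Replicate-to-replicate variation in
transcript proportions is modelled with a Dirichlet draw around the
condition's mean proportions (concentration = ``overdispersion``; larger
means tighter replicates), per-sample sequencing depth with a
negative-binomial draw, and read allocation to junctions with a
multinomial.  This Dirichlet-multinomial-over-transcripts construction is
the minimal standard model producing overdispersed compositional counts
with transcript-mixture covariance.

A differential gene differs between conditions only in its transcript
proportions; ``effect`` is the total-variation distance between the two
proportion vectors, so one scalar summarizes usage shift while expression
level stays constant in expectation.

All randomness flows from a single root seed: the stream for gene ``g``,
condition ``c``, replicate ``r`` is seeded by
``(seed, crc32(g), {A:0, B:1}[c], r)`` via :class:`numpy.random.SeedSequence`,
so every count vector is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import JunctionCountMatrix, JunctionID, SequenceRecord

__all__ = [
    "SimGeneSpec",
    "SimConfig",
    "SimTruth",
    "simulate_gene",
    "simulate_dataset",
    "simulate_sequences",
    "random_gene_spec",
]

_COND_CODE = {"A": 0, "B": 1}

PAS_MOTIF = "AATAAA"
_PAS_RC = "TTTATT"


@dataclass
class SimGeneSpec:
    """Ground-truth description of one simulated gene.

    ``transcripts`` is a transcript x junction 0/1 incidence matrix;
    ``base_props``/``alt_props`` are the transcript proportions in
    conditions A and B.  ``effect`` is their total-variation distance.
    """

    gene: str
    n_junctions: int
    transcripts: np.ndarray
    base_props: np.ndarray
    alt_props: np.ndarray

    def __post_init__(self) -> None:
        self.transcripts = np.asarray(self.transcripts, dtype=float)
        self.base_props = np.asarray(self.base_props, dtype=float)
        self.alt_props = np.asarray(self.alt_props, dtype=float)
        if self.n_junctions < 1:
            raise ValueError("n_junctions must be >= 1")
        if self.transcripts.ndim != 2 or self.transcripts.shape[1] != self.n_junctions:
            raise ValueError("transcripts must be a transcripts x junctions incidence matrix")
        if np.any((self.transcripts != 0) & (self.transcripts != 1)):
            raise ValueError("incidence entries must be 0 or 1")
        if np.any(self.transcripts.sum(axis=1) < 1):
            raise ValueError("every transcript must use at least one junction")
        if np.any(self.transcripts.sum(axis=0) < 1):
            raise ValueError("every junction must be used by at least one transcript")
        for name, props in (("base_props", self.base_props), ("alt_props", self.alt_props)):
            if props.shape != (self.transcripts.shape[0],):
                raise ValueError(f"{name} must have one entry per transcript")
            if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be non-negative and sum to 1")

    @property
    def effect(self) -> float:
        """Total-variation distance between condition proportions."""
        return 0.5 * float(np.abs(self.base_props - self.alt_props).sum())

    @property
    def is_differential(self) -> bool:
        return self.effect > 0

    def junction_probs(self, theta: np.ndarray) -> np.ndarray:
        """Expected per-junction read shares for transcript proportions theta."""
        w = theta @ self.transcripts
        return w / w.sum()


@dataclass
class SimConfig:
    """Study conditions for a simulated two-group junction experiment.

    Defaults describe a modest bulk RNA-seq design: three replicates per
    condition, a few hundred junction-spanning reads per gene and sample,
    genes of 3-6 junctions, moderate biological overdispersion.
    """

    n_genes: int = 100
    frac_differential: float = 0.2
    n_r: int = 3
    depth_mean: float = 300.0
    depth_dispersion: float = 10.0
    overdispersion: float = 50.0
    effect: float = 0.5
    min_junctions: int = 3
    max_junctions: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_r < 2:
            raise ValueError("need n_genes >= 1 and n_r >= 2")
        if not 0 <= self.frac_differential <= 1:
            raise ValueError("frac_differential must be in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0 or self.overdispersion <= 0:
            raise ValueError("depth and dispersion parameters must be positive")
        if not 0 <= self.effect <= 1:
            raise ValueError("effect must be in [0, 1]")
        if not 1 <= self.min_junctions <= self.max_junctions:
            raise ValueError("need 1 <= min_junctions <= max_junctions")


@dataclass
class SimTruth:
    """Which simulated genes are truly differential, and how."""

    specs: dict[str, SimGeneSpec] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.specs),
                "is_differential": [s.is_differential for s in self.specs.values()],
                "effect": [s.effect for s in self.specs.values()],
                "n_junctions": [s.n_junctions for s in self.specs.values()],
            }
        )


def _gene_stream(seed: int, gene: str, condition: str, replicate_index: int) -> np.random.Generator:
    key = (seed, zlib.crc32(gene.encode()), _COND_CODE[condition], replicate_index)
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_gene(
    spec: SimGeneSpec,
    cfg: SimConfig,
    condition: str,
    replicate_index: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one replicate's junction count vector for one gene.

    Transcript proportions are drawn from a Dirichlet centred on the
    condition's proportions with concentration ``cfg.overdispersion``
    (``overdispersion = inf`` fixes them exactly); total depth from a
    negative binomial with mean ``depth_mean`` and dispersion
    ``depth_dispersion`` (variance ``m + m^2/phi``; ``inf`` fixes the
    depth); counts from a multinomial over the per-junction read shares
    implied by the transcript incidence matrix.
    """
    if condition not in _COND_CODE:
        raise ValueError("condition must be 'A' or 'B'")
    if rng is None:
        rng = _gene_stream(cfg.seed, spec.gene, condition, replicate_index)
    props = spec.base_props if condition == "A" else spec.alt_props
    if np.isinf(cfg.overdispersion):
        theta = props
    else:
        alpha = props * cfg.overdispersion
        # Dirichlet needs strictly positive concentrations; a tiny floor
        # keeps zero-proportion transcripts effectively absent.
        theta = rng.dirichlet(np.maximum(alpha, 1e-9))
    probs = spec.junction_probs(theta)
    if np.isinf(cfg.depth_dispersion):
        depth = int(round(cfg.depth_mean))
    else:
        phi = cfg.depth_dispersion
        depth = int(rng.negative_binomial(phi, phi / (phi + cfg.depth_mean)))
    return rng.multinomial(depth, probs)


def _tilt_props(base: np.ndarray, effect: float) -> np.ndarray:
    """Shift probability mass ``effect`` toward one recipient transcript.

    Mass is drained from the other transcripts in descending order of
    abundance until exactly ``effect`` has moved, so the total-variation
    distance between base and tilted proportions equals the requested
    effect (capped at the mass available outside the recipient).
    """
    if effect == 0:
        return base.copy()
    k = base.size
    if k < 2:
        raise ValueError("a differential gene needs at least two transcripts")
    recipient = int(np.argmin(base))
    alt = base.copy()
    remaining = min(effect, float(base.sum() - base[recipient]))
    for donor in np.argsort(-base):
        if donor == recipient or remaining <= 0:
            continue
        moved = min(remaining, alt[donor])
        alt[donor] -= moved
        alt[recipient] += moved
        remaining -= moved
    return alt


def random_gene_spec(
    gene: str,
    rng: np.random.Generator,
    n_junctions: int,
    differential: bool,
    effect: float,
) -> SimGeneSpec:
    """Draw a random transcript structure and proportions for one gene.

    Transcripts are random junction subsets (2-4 transcripts, each junction
    included with probability 1/2, coverage repaired so every junction is
    used); base proportions are a Dirichlet(5) draw, which keeps all
    transcripts expressed at comparable levels.
    """
    # cannot ask for more distinct transcripts than non-empty junction subsets
    n_tx = min(int(rng.integers(2, 5)), 2**n_junctions - 1)
    if n_tx < 2:
        differential = False
    while True:
        inc = (rng.random((n_tx, n_junctions)) < 0.5).astype(float)
        for t in range(n_tx):
            if inc[t].sum() == 0:
                inc[t, rng.integers(n_junctions)] = 1.0
        uncovered = np.flatnonzero(inc.sum(axis=0) == 0)
        for j in uncovered:
            inc[rng.integers(n_tx), j] = 1.0
        # distinct transcripts make the mixture identifiable
        if len({tuple(row) for row in inc}) == n_tx:
            break
    base = rng.dirichlet(np.full(n_tx, 5.0))
    alt = _tilt_props(base, effect) if differential else base.copy()
    return SimGeneSpec(
        gene=gene, n_junctions=n_junctions, transcripts=inc, base_props=base, alt_props=alt
    )


def simulate_dataset(cfg: SimConfig) -> tuple[JunctionCountMatrix, SimTruth]:
    """Simulate a full two-condition junction-count experiment.

    Samples are named ``A_1..A_nr`` and ``B_1..B_nr``; each gene is truly
    differential with probability ``frac_differential`` (usage shift of
    size ``cfg.effect``), and the per-gene ground truth is recorded in the
    returned :class:`SimTruth`.
    """
    root = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xD5)))
    samples = [f"A_{i + 1}" for i in range(cfg.n_r)] + [f"B_{i + 1}" for i in range(cfg.n_r)]
    condition_of = {s: s[0] for s in samples}
    truth = SimTruth()
    junctions: list[JunctionID] = []
    rows: list[np.ndarray] = []
    for g in range(cfg.n_genes):
        gene = f"GENE{g + 1:04d}"
        # The gene panel (sizes, transcript structures, baseline proportions)
        # is a fixed property of the configuration, like a genome: its
        # stream is keyed by gene index only, so different seeds resample
        # the experiment over identical dimensions.
        panel_rng = np.random.default_rng(np.random.SeedSequence((0x9A7E1, g)))
        n_j = int(panel_rng.integers(cfg.min_junctions, cfg.max_junctions + 1))
        differential = bool(root.random() < cfg.frac_differential)
        spec = random_gene_spec(gene, panel_rng, n_j, differential, cfg.effect)
        truth.specs[gene] = spec
        block = np.zeros((n_j, len(samples)), dtype=np.int64)
        for si, sample in enumerate(samples):
            cond = condition_of[sample]
            rep = int(sample.split("_")[1]) - 1
            block[:, si] = simulate_gene(spec, cfg, cond, rep)
        rows.append(block)
        base = 1 + g * 100_000
        junctions.extend(
            JunctionID(
                chrom="chrS",
                start=base + j * 1_000,
                end=base + j * 1_000 + 500,
                gene=gene,
            )
            for j in range(n_j)
        )
    counts = np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int64)
    return JunctionCountMatrix(junctions, samples, counts, condition_of), truth


def _scrub(seq: list[str], rng: np.random.Generator, protect: tuple[int, int] | None = None) -> None:
    """Remove all PAS occurrences (both strands) by redrawing bases in place."""
    patterns = (PAS_MOTIF, _PAS_RC)
    while True:
        text = "".join(seq)
        hit = -1
        for pat in patterns:
            pos = text.find(pat)
            while pos != -1:
                if protect is None or not (protect[0] <= pos < protect[1]):
                    hit = pos
                    break
                pos = text.find(pat, pos + 1)
            if hit != -1:
                break
        if hit == -1:
            return
        # redraw a base of the offending occurrence that lies outside the
        # protected (planted) region
        redraw = hit + 5
        if protect is not None and protect[0] <= redraw < protect[1]:
            redraw = hit
        seq[redraw] = "ACGT"[rng.integers(4)]


def simulate_sequences(
    junctions: list[JunctionID],
    plant_motif: list[bool],
    window: int = 500,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Random gene-region sequences with AATAAA planted or scrubbed.

    For each junction a uniform-random DNA background covering
    ``[start - window, end + window]`` (clipped at coordinate 1) is drawn.
    When ``plant_motif`` is true an AATAAA hexamer is written at a random
    position within ``window`` of the junction start; otherwise every
    AATAAA/TTTATT occurrence is scrubbed from the background, so a
    both-strand scan finds no hit.  Records are named by gene symbol.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(plant_motif) != len(junctions):
        raise ValueError("plant_motif must have one flag per junction")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5E0)))
    records: list[SequenceRecord] = []
    for junction, plant in zip(junctions, plant_motif):
        lo = max(1, junction.start - window)
        hi = junction.end + window
        seq = list("ACGT"[i] for i in rng.integers(4, size=hi - lo + 1))
        if plant:
            pos_lo = max(lo, junction.start - window) - lo
            pos_hi = min(hi - 5, junction.start + window - 5) - lo
            pos = int(rng.integers(pos_lo, pos_hi + 1))
            seq[pos : pos + 6] = list(PAS_MOTIF)
            _scrub(seq, rng, protect=(pos, pos + 6))
        else:
            _scrub(seq, rng)
        records.append(SequenceRecord(junction.gene, "".join(seq), offset=lo))
    return records
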