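"""Synthetic genome-pair / clade simulator with known ground truth.

Descendant genomes are drawn from a shared ancestor gene pool on a star
phylogeny. ``p_sub`` is the expected per-site divergence between any two
descendants. Each lineage independently substitutes each site with a
probability q chosen so that the two-lineage process (including the chance
that both lineages collide on the same derived base) realizes exactly that
divergence:

    (1 - q)^2 + c * q^2 = 1 - p_sub,
    q = (1 - sqrt(1 - (1 + c) * p_sub)) / (1 + c),
    c = (kappa^2 + 1/2) / (kappa + 1)^2,

with kappa the transition/transversion ratio (c = 1/2 at kappa = 2); c q^2
is the back-mutation/collision term. Substitutions are independent per-site
Bernoulli draws, not a continuous-time model, so E[identity] = 1 - p_sub
holds exactly. Divergences beyond the model's saturation point,
p_sub > 1/(1 + c), are rejected.

Optional per-lineage gene loss, Poisson gene gain (novel random genes,
guaranteed ORFan analogues at desk scale), and one codon-length indel per
gene per lineage with probability ``p_indel``.

Ancestor and novel genes are sampled stop-free (stop codons rejected at
generation time); lineage mutation is unconditioned, so a descendant CDS
may acquire internal stop codons, which appear as '*' in its protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .pairwise import ScoringScheme, nw_align
from .seqio import Gene, GeneSet, SequenceRecord, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODON_TABLE: dict[str, str] = {}
_STOPS = ("TAA", "TAG", "TGA")
# transition partner per base index (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.int64)
_TRANSVERSIONS = np.array(
    [[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int64
)


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def _translate(nt: str) -> str:
    table = _codon_table()
    return "".join(
        table.get(nt[i:i + 3], "X") for i in range(0, len(nt) - 2, 3)
    )


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run; a fixed seed gives byte-identical
    output files."""

    n_genes: int = 100
    p_sub: float = 0.1  # expected per-site divergence between descendants
    ts_tv_ratio: float = 2.0
    p_indel: float = 0.0  # per-gene per-lineage one codon-length indel
    loss_rate: float = 0.0  # per-gene per-lineage loss probability
    gain_rate: float = 0.0  # expected novel genes per lineage (Poisson)
    length_min: int = 300  # gene lengths: uniform multiples of 3 in range
    length_max: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        for name in ("p_sub", "p_indel", "loss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must lie in [0, 1]")
        if self.gain_rate < 0:
            raise SimulationError("gain_rate must be >= 0")
        if self.ts_tv_ratio <= 0:
            raise SimulationError("ts_tv_ratio must be positive")
        if not (3 <= self.length_min <= self.length_max):
            raise SimulationError("bad gene length range")
        if self.length_min % 3 or self.length_max % 3:
            raise SimulationError("gene length bounds must be codon multiples")
        c = _collision_prob(self.ts_tv_ratio)
        if (1.0 + c) * self.p_sub > 1.0:
            raise SimulationError(
                f"p_sub={self.p_sub} exceeds the model's saturation "
                f"divergence {1.0 / (1.0 + c):.3f}"
            )

    @property
    def per_lineage_rate(self) -> float:
        """Per-site substitution probability applied on each branch."""
        c = _collision_prob(self.ts_tv_ratio)
        return (1.0 - math.sqrt(1.0 - (1.0 + c) * self.p_sub)) / (1.0 + c)


def _collision_prob(ts_tv_ratio: float) -> float:
    """P(two lineages pick the same derived base | both substitute)."""
    k = ts_tv_ratio
    return (k * k + 0.5) / ((k + 1.0) ** 2)


def expected_pair_identity(p_sub: float, ts_tv_ratio: float = 2.0) -> float:
    """Closed-form expected per-site identity between two descendants
    (fraction in [0, 1]): equals 1 - p_sub by construction; see module
    docstring."""
    c = _collision_prob(ts_tv_ratio)
    q = (1.0 - math.sqrt(1.0 - (1.0 + c) * p_sub)) / (1.0 + c)
    return (1.0 - q) ** 2 + c * q * q


@dataclass
class CladeTruth:
    """Ground truth for a simulated clade."""

    # per-genome: ancestor gene id -> descendant gene id (retained genes)
    retained: list[dict[str, str]]
    # per-genome: ids of novel (gained) genes
    novel: list[set[str]]

    def pair_ortholog_map(self, i: int, j: int) -> dict[str, str]:
        """True ortholog map between genomes i and j (gene_i -> gene_j)."""
        ri, rj = self.retained[i], self.retained[j]
        return {ri[anc]: rj[anc] for anc in ri if anc in rj}

    def lineage_specific(self, i: int, j: int) -> tuple[set[str], set[str]]:
        """Genes of i and of j without a counterpart in the other genome
        (novel genes plus genes whose ortholog was lost)."""
        ri, rj = self.retained[i], self.retained[j]
        only_i = {ri[a] for a in ri if a not in rj} | self.novel[i]
        only_j = {rj[a] for a in rj if a not in ri} | self.novel[j]
        return only_i, only_j


@dataclass
class SimulatedPair:
    geneset_a: GeneSet
    geneset_b: GeneSet
    ortholog_map: dict[str, str]  # gene_a -> gene_b, 1:1
    realized_identity: dict[str, float]  # keyed by gene_a, percent
    lineage_specific_a: set[str]
    lineage_specific_b: set[str]
    novel_a: set[str]
    novel_b: set[str]
    config: SimulationConfig = field(default=None)  # type: ignore


def _random_gene(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random coding sequence without stop codons, as base indices 0-3."""
    arr = rng.integers(0, 4, size=length)
    _purge_stops(arr, rng)
    return arr


def _purge_stops(arr: np.ndarray, rng: np.random.Generator) -> None:
    letters = _BASES[arr].tobytes().decode()
    for i in range(0, len(arr) - 2, 3):
        while letters[i:i + 3] in _STOPS:
            arr[i:i + 3] = rng.integers(0, 4, size=3)
            letters = (letters[:i] +
                       _BASES[arr[i:i + 3]].tobytes().decode() +
                       letters[i + 3:])


def _mutate(arr: np.ndarray, q: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Per-site Bernoulli substitutions with transition bias.

    Substitutions are unconditioned (a mutated codon may become a stop;
    proteins then carry '*', which the protein alphabet and BLOSUM62 both
    accommodate) so realized identity follows the exact binomial closed
    form used by the validation oracles.
    """
    out = arr.copy()
    mask = rng.random(arr.shape[0]) < q
    idx = np.nonzero(mask)[0]
    if idx.size:
        is_ts = rng.random(idx.size) < kappa / (kappa + 1.0)
        tv_choice = rng.integers(0, 2, size=idx.size)
        anc = out[idx]
        new = np.where(
            is_ts, _TRANSITION[anc],
            _TRANSVERSIONS[anc, tv_choice],
        )
        out[idx] = new
    return out


def _apply_indel(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One codon-length (3 nt) insertion or deletion at a codon boundary."""
    n_codons = arr.shape[0] // 3
    if rng.random() < 0.5 and n_codons > 1:  # deletion
        pos = int(rng.integers(0, n_codons))
        return np.concatenate([arr[:pos * 3], arr[(pos + 1) * 3:]])
    pos = int(rng.integers(0, n_codons + 1))
    codon = _random_gene(rng, 3)
    return np.concatenate([arr[:pos * 3], codon, arr[pos * 3:]])


def _to_gene(gene_id: str, arr: np.ndarray) -> Gene:
    nt = _BASES[arr].tobytes().decode()
    aa = _translate(nt)
    return Gene(
        gene_id=gene_id,
        cds=SequenceRecord(id=gene_id, residues=nt, alphabet="nucleotide"),
        protein=SequenceRecord(id=gene_id, residues=aa, alphabet="protein"),
    )


def simulate_clade(n_genomes: int, config: SimulationConfig,
                   genome_ids: Optional[list[str]] = None
                   ) -> tuple[list[GeneSet], CladeTruth]:
    """Simulate ``n_genomes`` descendants of one ancestor gene pool on a
    star phylogeny, with per-lineage substitution, optional indels, gene
    loss and gene gain."""
    if n_genomes < 2:
        raise SimulationError("need at least 2 genomes")
    if genome_ids is None:
        genome_ids = [f"sim{i + 1}" for i in range(n_genomes)]
    if len(genome_ids) != n_genomes:
        raise SimulationError("one genome_id per genome required")

    rng = np.random.default_rng(config.seed)
    q = config.per_lineage_rate
    kappa = config.ts_tv_ratio

    n_codons = rng.integers(
        config.length_min // 3, config.length_max // 3 + 1,
        size=config.n_genes,
    )
    ancestor = [
        (f"anc{i + 1:05d}", _random_gene(rng, int(nc) * 3))
        for i, nc in enumerate(n_codons)
    ]

    genesets: list[GeneSet] = []
    retained: list[dict[str, str]] = []
    novel: list[set[str]] = []
    for gid in genome_ids:
        genes: list[Gene] = []
        kept: dict[str, str] = {}
        for anc_id, anc_arr in ancestor:
            if config.loss_rate > 0 and rng.random() < config.loss_rate:
                continue
            arr = _mutate(anc_arr, q, kappa, rng)
            if config.p_indel > 0 and rng.random() < config.p_indel:
                arr = _apply_indel(arr, rng)
            gene_id = f"{gid}_{anc_id}"
            genes.append(_to_gene(gene_id, arr))
            kept[anc_id] = gene_id
        gained: set[str] = set()
        n_gain = int(rng.poisson(config.gain_rate)) if config.gain_rate else 0
        for k in range(n_gain):
            nc = int(rng.integers(
                config.length_min // 3, config.length_max // 3 + 1
            ))
            gene_id = f"{gid}_novel{k + 1:04d}"
            genes.append(_to_gene(gene_id, _random_gene(rng, nc * 3)))
            gained.add(gene_id)
        if not genes:
            raise SimulationError(
                f"lineage {gid} lost every gene; lower loss_rate"
            )
        genesets.append(GeneSet(genome_id=gid, genes=genes))
        retained.append(kept)
        novel.append(gained)

    return genesets, CladeTruth(retained=retained, novel=novel)


def simulate_pair(config: SimulationConfig,
                  genome_ids: tuple[str, str] = ("simA", "simB")
                  ) -> SimulatedPair:
    """Simulate one genome pair with full ground truth (ortholog map,
    realized per-pair identities, lineage-specific gene sets)."""
    genesets, truth = simulate_clade(2, config, list(genome_ids))
    set_a, set_b = genesets
    omap = truth.pair_ortholog_map(0, 1)
    genes_a = {g.gene_id: g for g in set_a}
    genes_b = {g.gene_id: g for g in set_b}
    scheme = ScoringScheme.nucleotide()
    realized: dict[str, float] = {}
    for ga, gb in omap.items():
        ca, cb = genes_a[ga].cds, genes_b[gb].cds
        if config.p_indel == 0.0:  # ungapped: per-site comparison suffices
            ident = sum(
                1 for x, y in zip(ca.residues, cb.residues) if x == y
            )
            realized[ga] = 100.0 * ident / len(ca)
        else:
            realized[ga] = nw_align(ca, cb, scheme).identity_pct
    only_a, only_b = truth.lineage_specific(0, 1)
    return SimulatedPair(
        geneset_a=set_a, geneset_b=set_b,
        ortholog_map=omap, realized_identity=realized,
        lineage_specific_a=only_a, lineage_specific_b=only_b,
        novel_a=truth.novel[0], novel_b=truth.novel[1],
        config=config,
    )


def write_simulation(genesets: list[GeneSet], truth: CladeTruth,
                     out_dir: str | Path) -> None:
    """Write per-genome .fna/.faa files plus truth.json."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for gs in genesets:
        write_fasta((g.cds for g in gs), out / f"{gs.genome_id}.fna")
        write_fasta((g.protein for g in gs), out / f"{gs.genome_id}.faa")
    payload = {
        "genomes": [gs.genome_id for gs in genesets],
        "retained": truth.retained,
        "novel": [sorted(s) for s in truth.novel],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
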