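"""Synthetic benchmark generator with planted block structure.

Proteins are partitioned into functional blocks, and every evidence
channel is a noisy view of that one latent structure:

* sequences are lightly mutated copies of a block-ancestral 60-mer, so
  local alignment genuinely recovers block membership;
* GO terms and Pfam domains are drawn from block-specific pools with mild
  background contamination;
* STRING lists every within-block pair plus a background fraction of
  between-block pairs (edge existence alone is noisy — the realistic
  STRING failure mode of promiscuous low-confidence edges), with
  confidence scores high (150-999) within blocks and low (0-400) between.

``noise_per_source`` gives, per channel, the fraction of proteins whose
measurement in that channel is uninformative: a fully random sequence,
annotation terms drawn from the global pool, or confidence scores drawn
uniformly over 0-999.  The unreliable subsets are drawn independently per
channel, so the four channels carry complementary information — the
regime network fusion is designed for.

lncRNAs are assigned to blocks and wired preferentially to same-block
proteins, which is the planted interaction signal every stage is judged
against.  Every lncRNA is guaranteed at least two partners so that
leave-one-out validation is well defined.  All output is a deterministic
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import InteractionTable, ProteinRecord, ScoredEdgeList

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_NOISE = {"Seqs": 0.4, "Go": 0.4, "Pfam": 0.4, "String": 0.4}


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-block benchmark."""

    n_proteins: int = 80
    n_lncrnas: int = 200
    n_blocks: int = 4
    noise_per_source: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    interaction_density_within: float = 0.15
    interaction_density_between: float = 0.01
    seed: int = 0
    ancestor_length: int = 60
    clean_mutation_rate: float = 0.1
    go_pool_per_block: int = 15
    go_terms_per_protein: int = 8
    pfam_pool_per_block: int = 8
    pfam_domains_per_protein: int = 4
    annotation_contamination: float = 0.1
    string_background_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")
        if not self.interaction_density_within > self.interaction_density_between:
            raise ValueError("within-block density must exceed between-block density")
        for src, p in self.noise_per_source.items():
            if not 0 <= p <= 1:
                raise ValueError(f"noise for {src} outside [0, 1]")


@dataclass
class SyntheticData:
    """In-memory view of one generated benchmark instance."""

    records: list[ProteinRecord]
    go_map: dict[str, set]
    pfam_map: dict[str, set]
    edges: ScoredEdgeList
    interactions: InteractionTable
    protein_blocks: dict[str, int]
    lncrna_blocks: dict[str, int]
    unreliable: dict[str, set]


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    return np.arange(n) % n_blocks


def _mutate(ancestor: str, rate: float, rng: np.random.Generator) -> str:
    seq = list(ancestor)
    for i in range(len(seq)):
        if rng.random() < rate:
            seq[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(seq)


def _draw_terms(
    n_terms: int,
    block_pool: list[str],
    background_pool: list[str],
    contamination: float,
    rng: np.random.Generator,
) -> set:
    terms = set()
    for _ in range(n_terms):
        pool = background_pool if rng.random() < contamination else block_pool
        terms.add(pool[rng.integers(len(pool))])
    return terms


def generate_tables(config: SyntheticConfig) -> SyntheticData:
    """Generate one benchmark instance in memory, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    nb = config.n_blocks
    noise = config.noise_per_source
    protein_ids = [f"P{i:04d}" for i in range(config.n_proteins)]
    lncrna_ids = [f"L{i:04d}" for i in range(config.n_lncrnas)]
    p_blocks = _block_assignment(config.n_proteins, nb)
    l_blocks = _block_assignment(config.n_lncrnas, nb)

    # Per-channel unreliable-protein masks, drawn independently per source.
    unreliable = {
        src: {pid for pid in protein_ids if rng.random() < noise.get(src, 0.0)}
        for src in ("Seqs", "Go", "Pfam", "String")
    }

    # Sequences: block ancestor lightly mutated; unreliable proteins random.
    ancestors = [
        "".join(AMINO_ACIDS[k] for k in rng.integers(len(AMINO_ACIDS), size=config.ancestor_length))
        for _ in range(nb)
    ]
    records = []
    for i, pid in enumerate(protein_ids):
        rate = 1.0 if pid in unreliable["Seqs"] else config.clean_mutation_rate
        records.append(ProteinRecord(id=pid, sequence=_mutate(ancestors[p_blocks[i]], rate, rng)))

    # GO / Pfam: block pools with mild contamination from the global pool;
    # unreliable proteins draw every term from the global pool.
    go_pools = [[f"GO:{b:02d}{t:04d}" for t in range(config.go_pool_per_block)] for b in range(nb)]
    go_background = [t for pool in go_pools for t in pool]
    go_map = {}
    for i, pid in enumerate(protein_ids):
        contamination = 1.0 if pid in unreliable["Go"] else config.annotation_contamination
        go_map[pid] = _draw_terms(config.go_terms_per_protein, go_pools[p_blocks[i]],
                                  go_background, contamination, rng)
    pfam_pools = [[f"PF{b:02d}{t:03d}" for t in range(config.pfam_pool_per_block)] for b in range(nb)]
    pfam_background = [d for pool in pfam_pools for d in pool]
    pfam_map = {}
    for i, pid in enumerate(protein_ids):
        contamination = 1.0 if pid in unreliable["Pfam"] else config.annotation_contamination
        pfam_map[pid] = _draw_terms(config.pfam_domains_per_protein, pfam_pools[p_blocks[i]],
                                    pfam_background, contamination, rng)

    # STRING: within-block pairs always listed, between-block pairs at the
    # background rate; scores by class.  A pair touching a protein that is
    # unreliable in this channel is garbled wholesale: listed with the
    # background probability regardless of class, score uniform over 0-999.
    string_edges: list[tuple[str, str, int]] = []
    for i in range(config.n_proteins):
        for j in range(i + 1, config.n_proteins):
            within = p_blocks[i] == p_blocks[j]
            garbled = (
                protein_ids[i] in unreliable["String"] or protein_ids[j] in unreliable["String"]
            )
            if garbled:
                if rng.random() >= config.string_background_rate:
                    continue
                score = int(rng.integers(0, 1000))
            else:
                if not within and rng.random() >= config.string_background_rate:
                    continue
                score = int(rng.integers(150, 1000)) if within else int(rng.integers(0, 401))
            string_edges.append((protein_ids[i], protein_ids[j], score))

    # Interactions: preferential wiring to the lncRNA's own block.
    pairs: set[tuple[str, str]] = set()
    for li, lid in enumerate(lncrna_ids):
        block = l_blocks[li]
        for pi, pid in enumerate(protein_ids):
            density = (
                config.interaction_density_within
                if p_blocks[pi] == block
                else config.interaction_density_between
            )
            if rng.random() < density:
                pairs.add((lid, pid))
        partners = {p for l, p in pairs if l == lid}
        candidates = [pid for pi, pid in enumerate(protein_ids)
                      if p_blocks[pi] == block and pid not in partners]
        if len(partners) + len(candidates) < 2:
            raise ValueError(
                f"config cannot guarantee 2 partners for {lid}: block too small"
            )
        while len(partners) < 2:
            choice = candidates.pop(int(rng.integers(len(candidates))))
            pairs.add((lid, choice))
            partners.add(choice)

    return SyntheticData(
        records=records,
        go_map=go_map,
        pfam_map=pfam_map,
        edges=ScoredEdgeList(edges=string_edges),
        interactions=InteractionTable.from_pairs(pairs),
        protein_blocks={pid: int(p_blocks[i]) for i, pid in enumerate(protein_ids)},
        lncrna_blocks={lid: int(l_blocks[i]) for i, lid in enumerate(lncrna_ids)},
        unreliable=unreliable,
    )


def generate(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the five input files consumed by the pipeline; byte-stable per seed."""
    data = generate_tables(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteins.fasta",
        "go": out / "go.tsv",
        "pfam": out / "pfam.tsv",
        "string": out / "string.tsv",
        "interactions": out / "interactions.tsv",
    }
    with open(paths["fasta"], "w", encoding="utf-8") as fh:
        for rec in data.records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    with open(paths["go"], "w", encoding="utf-8") as fh:
        for pid in sorted(data.go_map):
            for term in sorted(data.go_map[pid]):
                fh.write(f"{pid}\t{term}\n")
    with open(paths["pfam"], "w", encoding="utf-8") as fh:
        for pid in sorted(data.pfam_map):
            for dom in sorted(data.pfam_map[pid]):
                fh.write(f"{pid}\t{dom}\n")
    with open(paths["string"], "w", encoding="utf-8") as fh:
        for a, b, score in data.edges.edges:
            fh.write(f"{a}\t{b}\t{score}\n")
    with open(paths["interactions"], "w", encoding="utf-8") as fh:
        for l, p in sorted(data.interactions.pairs):
            fh.write(f"{l}\t{p}\n")
    return paths


def planted_truth(config: SyntheticConfig) -> tuple[InteractionTable, dict[str, int]]:
    """The ground-truth wiring and protein block assignment for a config/seed."""
    data = generate_tables(config)
    return data.interactions, data.protein_blocks
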