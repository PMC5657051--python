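"""End-to-end wiring: files or synthetic data -> source matrices -> experiments."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from . import data_io, evaluation, similarity
from .hetesim import InteractionMatrix
from .similarity import ScoringConfig, SimilarityMatrix
from .synthetic import SyntheticData


def build_source_matrices(
    records,
    go_map: Mapping[str, set],
    pfam_map: Mapping[str, set],
    edges,
    index,
    scoring: ScoringConfig | None = None,
) -> dict[str, SimilarityMatrix]:
    """Compute the four protein similarity networks over one protein index."""
    return {
        "Seqs": similarity.sequence_similarity(records, index, scoring=scoring),
        "Go": similarity.jaccard_similarity(go_map, index, "Go"),
        "Pfam": similarity.jaccard_similarity(pfam_map, index, "Pfam"),
        "String": similarity.string_similarity(edges, index),
    }


def load_inputs(
    interactions_path: str | Path,
    fasta_path: str | Path,
    go_path: str | Path,
    pfam_path: str | Path,
    string_path: str | Path,
    min_partners: int = 2,
    scoring: ScoringConfig | None = None,
) -> tuple[InteractionMatrix, dict[str, SimilarityMatrix]]:
    """Read the five input files, filter, and build the experiment inputs."""
    interactions = data_io.read_pair_table(interactions_path, kind="interactions")
    interactions = data_io.filter_interactions(interactions, min_partners=min_partners)
    records = data_io.read_fasta(fasta_path)
    go_map = data_io.read_pair_table(go_path, kind="annotations")
    pfam_map = data_io.read_pair_table(pfam_path, kind="annotations")
    edges = data_io.read_string_edges(string_path)
    universe = data_io.align_universe(records, interactions, edges, go_map, pfam_map)
    lp = InteractionMatrix.from_table(
        interactions, universe.lncrna_index, universe.protein_index
    )
    sources = build_source_matrices(
        records, go_map, pfam_map, edges, universe.protein_index, scoring=scoring
    )
    return lp, sources


def from_synthetic(
    data: SyntheticData, min_partners: int = 2, scoring: ScoringConfig | None = None
) -> tuple[InteractionMatrix, dict[str, SimilarityMatrix]]:
    """Build experiment inputs directly from an in-memory synthetic instance."""
    interactions = data_io.filter_interactions(data.interactions, min_partners=min_partners)
    universe = data_io.align_universe(
        data.records, interactions, data.edges, data.go_map, data.pfam_map
    )
    lp = InteractionMatrix.from_table(
        interactions, universe.lncrna_index, universe.protein_index
    )
    sources = build_source_matrices(
        data.records, data.go_map, data.pfam_map, data.edges, universe.protein_index,
        scoring=scoring,
    )
    return lp, sources


def benchmark_aucs(
    config, n_seeds: int = 10, base_seed: int = 0, **setting_kwargs
) -> dict[str, list[float]]:
    """Mean-AUC benchmark over seeds: every setting's AUC per generated instance."""
    from dataclasses import replace

    from .synthetic import generate_tables

    aucs: dict[str, list[float]] = {}
    for s in range(n_seeds):
        data = generate_tables(replace(config, seed=base_seed + s))
        lp, sources = from_synthetic(data)
        results = evaluation.run_all_settings(lp, sources, **setting_kwargs)
        for name, res in results.items():
            aucs.setdefault(name, []).append(res.auc)
    return aucs
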