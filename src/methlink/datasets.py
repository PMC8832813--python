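"""Packaged miniature pathway-style gene-set collections.

Real pathway databases are optional external adapters; the toy builder
below produces a deterministic class/subclass-structured collection over
an arbitrary gene universe, sized for tests and the synthetic pipeline.
"""

from __future__ import annotations

import numpy as np

from .enrichment import GeneSet, GeneSetCollection

_CLASSES = (
    ("Metabolism", ("Amino acid metabolism", "Lipid metabolism")),
    ("Genetic Information Processing", ("Replication and repair",
                                        "Translation")),
    ("Environmental Information Processing", ("Signal transduction",
                                              "Membrane transport")),
)


def toy_gene_sets(
    universe,
    n_sets: int = 12,
    min_size: int = 4,
    max_size: int = 12,
    seed: int = 0,
) -> GeneSetCollection:
    """A deterministic KEGG-like collection: ids PW0001.., names, classes
    and subclasses cycling through a fixed hierarchy."""
    rng = np.random.default_rng(seed)
    universe = sorted(universe)
    max_size = min(max_size, len(universe))
    min_size = min(min_size, max_size)
    sets = {}
    flat = [
        (cls, sub) for cls, subs in _CLASSES for sub in subs
    ]
    for i in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = rng.choice(universe, size=size, replace=False)
        cls, sub = flat[i % len(flat)]
        sid = f"PW{i + 1:04d}"
        sets[sid] = GeneSet(
            set_id=sid,
            name=f"pathway {i + 1}",
            genes=frozenset(str(g) for g in members),
            class_=cls,
            subclass=sub,
        )
    return GeneSetCollection(sets=sets, universe=frozenset(universe))
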