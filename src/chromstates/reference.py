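"""Published reference constants for the human K562 epigenome at 100 kb resolution.

These numbers summarize a genome-wide five-way classification of 100 kb
windows into four prevalent chromatin states plus an unclassified rest:

* ``C1`` — transcriptionally active open euchromatin (early replicating),
* ``C2`` — Polycomb-repressed facultative heterochromatin (mid-S),
* ``C3`` — unmarked silent chromatin (late),
* ``C4`` — HP1/H3K9me3 constitutive heterochromatin (very late),
* ``D``  — windows not confidently assigned to any state.

They serve two purposes in this package: as defaults for the synthetic
epigenome generator (so simulated genomes have realistic state structure)
and as inputs for the analytic block-length predictions.
"""

from __future__ import annotations

import numpy as np

#: Canonical state order used everywhere in the package.
STATES: tuple[str, ...] = ("C1", "C2", "C3", "C4", "D")

#: Marginal probability of each state over classified 100 kb windows (K562).
K562_STATE_PROBS = np.array([0.22, 0.18, 0.22, 0.22, 0.16])

#: First-order Markov transition probabilities between the states of
#: neighboring 100 kb windows in K562 (row = from-state, column = to-state,
#: order C1, C2, C3, C4, D).  Rows are printed at limited precision and sum
#: to 0.999-1.004; renormalize before sampling.
K562_TRANSITION_PROBS = np.array(
    [
        [0.59, 0.21, 0.082, 0.024, 0.094],
        [0.27, 0.51, 0.097, 0.017, 0.11],
        [0.084, 0.078, 0.65, 0.079, 0.11],
        [0.024, 0.013, 0.077, 0.85, 0.035],
        [0.13, 0.12, 0.15, 0.05, 0.55],
    ]
)

#: Gene (promoter) density per Mb of state territory in K562, C1..C4.
K562_GENE_DENSITY_PER_MB = {"C1": 19.1, "C2": 7.7, "C3": 4.1, "C4": 1.8}

#: ChIP-seq targets profiled in the K562 configuration (13 marks).
K562_MARKS: tuple[str, ...] = (
    "CTCF",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "H3K4me3",
    "H3K9me3",
    "RNAPII",
    "H2AZ",
    "H3K79me2",
    "H3K9me1",
    "H4K20me1",
    "CBX3",
    "Sin3A",
)

#: Default role assignment of marks used to name clusters as chromatin states.
DEFAULT_MARK_ROLES = {
    "active": ("H3K4me3", "H3K27ac", "H3K36me3", "H3K79me2", "RNAPII"),
    "polycomb": ("H3K27me3",),
    "hp1": ("H3K9me3",),
}


def renormalized_transition_matrix(P: np.ndarray | None = None) -> np.ndarray:
    """Return ``P`` with each row rescaled to sum exactly to 1.

    Defaults to the K562 transition matrix, whose printed rows sum to
    0.999-1.004 because of rounding.
    """
    if P is None:
        P = K562_TRANSITION_PROBS
    P = np.asarray(P, dtype=float)
    return P / P.sum(axis=1, keepdims=True)
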