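"""Group-specific networks: PPI intersection and ΔPCC aggregation.

Each clinical group's network averages the ΔPCC of its member samples' PPI-
restricted sample-specific networks. An edge absent from a sample contributes
0, so the weight is

    w(edge) = Σ_{i=1..N} ΔPCC_i(edge) / N,

with N the full group size — averaging with zero-fill is a contraction, so
|w| never exceeds the largest contributing |ΔPCC|. Inside cross-validation a
group gets one network per training fold; the fold networks are averaged
(again with zero-fill) into the single stage-specific network.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Pair, PPINetwork
from .ssn import SampleSpecificNetwork


@dataclass
class GroupSpecificNetwork:
    group: str
    n_samples: int
    weights: dict[Pair, float]


def intersect_ppi(ssn: SampleSpecificNetwork, ppi: PPINetwork) -> SampleSpecificNetwork:
    """Restrict an SSN to the experimentally validated (PPI) edges."""
    return SampleSpecificNetwork(
        sample_id=ssn.sample_id,
        edges={pair: val for pair, val in ssn.edges.items() if pair in ppi},
    )


def aggregate_group(ssns: list[SampleSpecificNetwork], group: str) -> GroupSpecificNetwork:
    """Average ΔPCC over the N group samples with zero-fill for absent edges."""
    if not ssns:
        raise ValueError(f"group {group!r}: cannot aggregate an empty SSN list")
    n = len(ssns)
    totals: dict[Pair, float] = {}
    for ssn in ssns:
        for pair, (delta, _p) in ssn.edges.items():
            totals[pair] = totals.get(pair, 0.0) + delta
    return GroupSpecificNetwork(group=group, n_samples=n,
                                weights={p: t / n for p, t in totals.items()})


def average_fold_gsns(gsns: list[GroupSpecificNetwork]) -> GroupSpecificNetwork:
    """Average per-fold networks of one group into its final network.

    Folds lacking an edge contribute weight 0 for it, mirroring the
    sample-level zero-fill.
    """
    if not gsns:
        raise ValueError("cannot average an empty GSN list")
    names = {g.group for g in gsns}
    if len(names) != 1:
        raise ValueError(f"fold GSNs mix groups: {sorted(names)}")
    k = len(gsns)
    totals: dict[Pair, float] = {}
    for g in gsns:
        for pair, w in g.weights.items():
            totals[pair] = totals.get(pair, 0.0) + w
    n_samples = max(g.n_samples for g in gsns)
    return GroupSpecificNetwork(group=gsns[0].group, n_samples=n_samples,
                                weights={p: t / k for p, t in totals.items()})


def check_gsn_within_ppi(gsn: GroupSpecificNetwork, ppi: PPINetwork) -> None:
    """Assert the structural invariant: GSN edges are a subset of the PPI."""
    stray = [p for p in gsn.weights if p not in ppi]
    if stray:
        raise AssertionError(
            f"group {gsn.group!r}: {len(stray)} edge(s) outside the PPI, e.g. {stray[:3]}"
        )


def write_gsn(gsn: GroupSpecificNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for (a, b), w in sorted(gsn.weights.items()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
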