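"""Integration of evidence streams into per-species-pair HTT calls.

A horizontal transfer between two species is supported by four computable
criteria, echoing the classical argument (anomalously similar TEs in
distant hosts, absence in closer relatives, discordant TE/species trees,
non-orthologous insertion sites):

* **identity**: the cross-species TE divergence ``te_k2p`` is far below the
  neutral expectation ``expected_K = 2 * rate * T`` for hosts that split
  ``T`` million years ago (default: at most half);
* **patchy**: some species closer to one of the pair than the pair are to
  each other lacks the element;
* **discordance**: the TE tree contradicts the species tree (RF > 0);
* **independence**: the pair shares no orthologous insertion site.

The verdict is deliberately conjunctive: identity alone never suffices; an
HTT call needs the identity criterion plus at least one corroborating
criterion.  Without a substitution rate the identity test is skipped and
HTT can still be called — flagged as weaker — when all three remaining
criteria agree.  A *vertical* verdict needs the divergence ratio to be
consistent with the host split and at least one shared orthologous
insertion.  The direction of transfer is never inferred; calls are
symmetric in the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .io_core import CallerConfig

__all__ = ["HTTEvidence", "HTTCall", "expected_k", "call_htt", "patchiness"]


def expected_k(T_mya: float, rate: float) -> float:
    """Expected neutral divergence (subs/site) between lineages split T MY ago."""
    if T_mya < 0 or rate < 0:
        raise ValueError("divergence time and rate must be non-negative")
    return 2.0 * rate * T_mya


@dataclass(frozen=True)
class HTTEvidence:
    """Evidence bundle for one species pair; None marks a missing stream."""

    species_a: str
    species_b: str
    te_identity: float | None = None       # cross-species representative identity
    te_k2p: float | None = None            # cross-species K2P (subs/site)
    species_T: float | None = None         # host divergence time, MYA
    rate: float | None = None              # neutral subs/site/MY (user supplied)
    discordant: bool | None = None
    patchy: bool | None = None
    shared_count: int | None = None

    @property
    def expected_K(self) -> float | None:
        if self.species_T is None or self.rate is None:
            return None
        return expected_k(self.species_T, self.rate)


@dataclass(frozen=True)
class HTTCall:
    verdict: str                            # HTT | vertical | inconclusive
    criteria_met: tuple[str, ...]
    ratio: float | None                     # te_k2p / expected_K
    reason: str = ""


def call_htt(evidence: HTTEvidence, config: CallerConfig | None = None) -> HTTCall:
    """Apply the decision rule to one evidence bundle.

    Missing evidence streams shrink the set of evaluable criteria; they are
    never fabricated in either direction.
    """
    cfg = config or CallerConfig()
    met: list[str] = []
    ratio = None
    identity_evaluable = False

    exp = evidence.expected_K
    if exp is not None and evidence.te_k2p is not None:
        if exp == 0.0:
            if evidence.te_k2p > 0:
                return HTTCall("inconclusive", (), None,
                               "zero expected divergence with nonzero TE divergence")
        else:
            identity_evaluable = True
            ratio = evidence.te_k2p / exp
            if ratio <= cfg.htt_ratio_max:
                met.append("identity")
    if evidence.patchy:
        met.append("patchy")
    if evidence.discordant:
        met.append("discordance")
    if evidence.shared_count is not None and evidence.shared_count <= cfg.shared_max:
        met.append("independence")

    corroborating = [c for c in met if c != "identity"]
    if "identity" in met and corroborating:
        return HTTCall("HTT", tuple(met), ratio)
    if not identity_evaluable and {"patchy", "discordance", "independence"} <= set(met):
        return HTTCall("HTT", tuple(met), ratio,
                       "weaker evidence: no rate supplied, identity criterion skipped")
    if (ratio is not None and ratio >= cfg.vertical_min
            and evidence.shared_count is not None and evidence.shared_count > 0):
        return HTTCall("vertical", tuple(met), ratio)
    return HTTCall("inconclusive", tuple(met), ratio)


def patchiness(
    species_tree: dendropy.Tree,
    te_presence: dict[str, bool],
    focal_pair: tuple[str, str],
) -> bool:
    """True when a species closer to either focal species than the focal pair
    are to each other lacks the element.

    Distances are patristic when every edge has a length, topological (edge
    count) otherwise.  ``te_presence`` must cover every leaf of the tree.
    """
    a, b = focal_pair
    labels = [leaf.taxon.label for leaf in species_tree.leaf_node_iter()]
    for sp in (a, b):
        if sp not in labels:
            raise KeyError(f"focal species {sp!r} not in species tree")
    missing = [l for l in labels if l not in te_presence]
    if missing:
        raise ValueError(f"presence flags missing for leaves: {missing}")

    weighted = all(
        e.length is not None for e in species_tree.preorder_edge_iter()
        if e.head_node is not species_tree.seed_node)
    pdm = species_tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in species_tree.taxon_namespace}

    def dist(x: str, y: str) -> float:
        if weighted:
            return pdm.patristic_distance(taxa[x], taxa[y])
        return pdm.path_edge_count(taxa[x], taxa[y])

    dab = dist(a, b)
    for x in labels:
        if x in (a, b) or te_presence[x]:
            continue
        if dist(x, a) < dab or dist(x, b) < dab:
            return True
    return False
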