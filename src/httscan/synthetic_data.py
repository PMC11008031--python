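"""Synthetic host genomes with TE insertions under known histories.

The generator is the generative twin of the analysis stack: host genomes
evolve along an ultrametric species tree under the Kimura 2-parameter
substitution process (independent sites, no indels outside insertion /
truncation events), and a hAT-style element — terminal inverted repeats,
an 8 bp target site duplication on insertion, optionally a long planted
ORF — is dropped in under two kinds of event:

* **vertical**: the element inserts on an internal branch (or above the
  root); every descendant species inherits an orthologous copy in the same
  flanking context, which then diverges along its own lineage;
* **horizontal**: the element arrives from an external donor pool on a
  terminal branch at a stated age; recipients get copies at independent
  positions whose divergence from the consensus reflects only the time
  since transfer, so two recipients of a transfer at age *t* show cross
  species TE divergence of about ``2 t`` regardless of host divergence.

Event ages are measured above the present in tree units; trees in millions
of years are converted with an explicit substitution rate.  All insertion
anchors are drawn in ancestral (root) coordinates with a global minimum
spacing so loci never interleave across lineages and every simulated locus
has clean 1.5 kb flanks — the regime the orthologous-site test assumes.
A per-copy truth table records coordinates, event, kind and true divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from . import _seq
from .io_core import GenomeRecord, Interval, read_newick

__all__ = [
    "SimConfig", "InsertionEvent", "TruthTable", "Scenario",
    "make_te_consensus", "insert_te", "evolve_seq", "simulate_scenario",
    "vertical_scenario", "htt_scenario", "htt_discordance_scenario",
    "presence_absence_scenario",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]


# ---------------------------------------------------------------------------
# K2P substitution process
# ---------------------------------------------------------------------------

def _k2p_probs(distance: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(total transversion)) after ``distance`` expected subs/site.

    ``kappa`` is the transition/transversion ratio R = alpha / (2 beta);
    kappa = 0.5 is the unbiased (Jukes-Cantor) limit.
    """
    b = distance / (2.0 * (kappa + 1.0))         # beta * t, per transversion type
    a = kappa * distance / (kappa + 1.0)          # alpha * t
    e4b = np.exp(-4.0 * b)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * np.exp(-2.0 * (a + b))
    p_tv = 0.5 - 0.5 * e4b
    return float(p_ts), float(p_tv)


def _evolve_arr(arr: np.ndarray, distance: float, kappa: float,
                rng: np.random.Generator) -> np.ndarray:
    if distance < 0:
        raise ValueError(f"negative distance: {distance}")
    out = arr.copy()
    if distance == 0 or arr.size == 0:
        return out
    p_ts, p_tv = _k2p_probs(distance, kappa)
    u = rng.random(arr.shape[0])
    acgt = arr < 4
    ts = acgt & (u < p_ts)
    tv1 = acgt & (u >= p_ts) & (u < p_ts + p_tv / 2)
    tv2 = acgt & (u >= p_ts + p_tv / 2) & (u < p_ts + p_tv)
    # code bit tricks: transition = ^2 (A<->G, C<->T); transversions = ^1, ^3
    out[ts] ^= 2
    out[tv1] ^= 1
    out[tv2] ^= 3
    return out


def evolve_seq(seq: str, distance: float, kappa: float = 2.0,
               seed: int | np.random.Generator = 0) -> str:
    """Evolve a sequence under the K2P process by ``distance`` expected subs/site."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _seq.decode(_evolve_arr(_seq.encode(seq), distance, kappa, rng))


# ---------------------------------------------------------------------------
# element construction and insertion
# ---------------------------------------------------------------------------

def make_te_consensus(
    te_length: int,
    tir_length: int = 15,
    seed: int | np.random.Generator = 0,
    gc: float = 0.44,
    orf_aa: int | None = None,
) -> str:
    """Build a hAT-style consensus: random interior, terminal inverted repeats,
    optionally a planted ORF of ``orf_aa`` residues (ATG..stop, sense codons).
    """
    if te_length <= 2 * tir_length:
        raise ValueError(
            f"te_length {te_length} must exceed twice tir_length {tir_length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = _seq.random_seq_arr(rng, te_length, gc)
    if orf_aa is not None and orf_aa > 0:
        orf_bp = 3 * orf_aa + 3                   # ATG + (orf_aa-1) codons + stop
        offset = tir_length + 6
        if offset + orf_bp > te_length - tir_length:
            raise ValueError(
                f"planted ORF of {orf_aa} aa does not fit in {te_length} bp element")
        codons = ["ATG"] + [
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), orf_aa - 1)
        ] + ["TAA"]
        arr[offset:offset + orf_bp] = _seq.encode("".join(codons))
    if tir_length > 0:
        arr[-tir_length:] = _seq.revcomp_arr(arr[:tir_length])
    return _seq.decode(arr)


def insert_te(
    genome: str,
    te_seq: str,
    position: int,
    tsd_length: int = 8,
    seq_id: str = "chr1",
) -> tuple[str, Interval, str]:
    """Insert a TE at ``position``, duplicating the ``tsd_length`` bp target site.

    Returns the grown genome, the interval of the TE itself (TSD copies
    excluded) and the duplicated target k-mer.  Genome length grows by
    ``len(te_seq) + tsd_length``.
    """
    if not (0 <= position and position + tsd_length <= len(genome)):
        raise ValueError(
            f"insertion position {position} (+{tsd_length} bp TSD) outside genome "
            f"of length {len(genome)}")
    tsd = genome[position:position + tsd_length]
    new = genome[:position + tsd_length] + te_seq + genome[position:]
    iv = Interval(seq_id, position + tsd_length, position + tsd_length + len(te_seq))
    return new, iv, tsd


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionEvent:
    """One insertion burst: vertical on a branch, or horizontal into recipients.

    ``age`` is measured above the present in tree units.  A vertical event
    names the clade (leaf set) below the target branch; an age at or above
    the root age inserts into the ancestral genome.  A horizontal event
    names recipient species; each gets copies at independent positions on
    its terminal branch.
    """

    kind: str                          # "vertical" | "horizontal"
    age: float
    clade: tuple[str, ...] = ()
    recipients: tuple[str, ...] = ()
    copies: int | None = None
    event_id: str = ""

    def __post_init__(self):
        if self.kind not in ("vertical", "horizontal"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "vertical" and not self.clade:
            raise ValueError("vertical event needs a clade")
        if self.kind == "horizontal" and not self.recipients:
            raise ValueError("horizontal event needs recipients")


@dataclass
class SimConfig:
    """Full scenario description; defaults are the package's study conditions."""

    species_tree: str                  # newick, lengths in `units`
    events: list[InsertionEvent]
    units: str = "subs"                # "subs" (subs/site) or "mya" (needs rate)
    rate: float | None = None          # substitutions/site/MY, for mya trees
    genome_length: int = 100_000
    gc_content: float = 0.44
    te_length: int = 3000
    tir_length: int = 15
    tsd_length: int = 8
    orf_aa: int | None = 620
    copies_per_event: int = 4
    fragment_prob: float = 0.2
    kappa: float = 2.0
    min_locus_spacing: int = 3500
    seed: int = 0
    n_species: int | None = None

    def __post_init__(self):
        if self.te_length <= 2 * self.tir_length:
            raise ValueError("te_length must exceed 2 * tir_length")
        if not (0.0 <= self.fragment_prob <= 1.0):
            raise ValueError("fragment_prob must be in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.units not in ("subs", "mya"):
            raise ValueError("units must be 'subs' or 'mya'")
        if self.units == "mya" and not self.rate:
            raise ValueError("an explicit substitution rate is required for MYA trees")


@dataclass
class TruthTable:
    """Ground truth: one row per realised copy, plus per-pair shared counts."""

    copies: pd.DataFrame
    shared_pairs: pd.DataFrame

    def shared_count(self, a: str, b: str) -> int:
        a, b = sorted((a, b))
        sel = self.shared_pairs[
            (self.shared_pairs.species_a == a) & (self.shared_pairs.species_b == b)]
        return int(sel.shared_count.iloc[0]) if len(sel) else 0


@dataclass
class Scenario:
    """A simulated dataset: per-species genomes, the element, and the truth."""

    config: SimConfig
    consensus: str
    genomes: dict[str, GenomeRecord]
    truth: TruthTable
    rate_scale: float                  # multiply tree units by this to get subs/site

    # -- convenience accessors ---------------------------------------------
    def copy_sequence(self, row) -> str:
        g = self.genomes[row.species].sequence
        return g[int(row.start):int(row.end)]

    def copy_flanks(self, row, pad: int = 30) -> tuple[str, str]:
        g = self.genomes[row.species].sequence
        s, e = int(row.start), int(row.end)
        return g[max(0, s - pad):s], g[e:e + pad]

    def te_intervals(self, species: str) -> list[Interval]:
        rows = self.truth.copies[self.truth.copies.species == species]
        return [Interval(r.seq_id, int(r.start), int(r.end)) for r in rows.itertuples()]

    def representative(self, species: str) -> str | None:
        """Least-diverged copy, preferring unfragmented ones."""
        rows = self.truth.copies[self.truth.copies.species == species]
        if rows.empty:
            return None
        rows = rows.sort_values(["fragment", "divergence"])
        return self.copy_sequence(rows.iloc[0])

    def species_with_te(self) -> list[str]:
        return sorted(self.truth.copies.species.unique())


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

@dataclass
class _CopyPlan:
    copy_id: str
    event_id: str
    kind: str
    age_subs: float
    anchor: int
    fragment: bool = False
    retained: float = 1.0
    trunc_side: str = ""


@dataclass
class _Placed:
    anchor: int
    added: int
    tsd_used: int
    te_len: int
    plan: _CopyPlan


def _node_ages(tree, scale: float) -> dict:
    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            cand = [
                ages[ch] + (ch.edge.length or 0.0) * scale for ch in node.child_nodes()]
            if max(cand) - min(cand) > 1e-6 * max(max(cand), 1e-12) + 1e-9:
                raise ValueError(
                    "species tree must be ultrametric for age-based events")
            ages[node] = float(np.mean(cand))
    return ages


def simulate_scenario(cfg: SimConfig) -> Scenario:
    """Run a full scenario and return genomes plus the truth table."""
    rng = np.random.default_rng(cfg.seed)
    tree = read_newick(cfg.species_tree)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if cfg.n_species is not None and cfg.n_species != len(leaves):
        raise ValueError(
            f"tree has {len(leaves)} leaves but n_species={cfg.n_species}")
    scale = 1.0 if cfg.units == "subs" else float(cfg.rate)
    ages = _node_ages(tree, scale)
    root = tree.seed_node
    root_age = ages[root]
    leafset = {
        node: frozenset(l.taxon.label for l in node.leaf_iter())
        for node in tree.preorder_node_iter()
    }

    consensus_arr = _seq.encode(
        make_te_consensus(cfg.te_length, cfg.tir_length, rng, cfg.gc_content, cfg.orf_aa))

    # -- resolve events onto branches, expanding horizontal recipients ------
    per_node: dict[int, list[tuple[float, list[_CopyPlan]]]] = {}
    node_by_id: dict[int, object] = {}
    plans: list[_CopyPlan] = []
    vertical_events: list[tuple[InsertionEvent, frozenset, int]] = []

    def _attach(node, age_subs, ev, tag, ncopies):
        node_by_id[id(node)] = node
        batch = []
        for i in range(ncopies):
            plan = _CopyPlan(
                copy_id=f"{tag}.{i}", event_id=ev.event_id or tag,
                kind=ev.kind, age_subs=age_subs, anchor=-1)
            if rng.random() < cfg.fragment_prob:
                plan.fragment = True
                plan.retained = float(rng.uniform(0.3, 0.9))
                plan.trunc_side = "left" if rng.random() < 0.5 else "right"
            batch.append(plan)
            plans.append(plan)
        per_node.setdefault(id(node), []).append((age_subs, batch))

    for e_idx, ev in enumerate(cfg.events):
        ncopies = ev.copies if ev.copies is not None else cfg.copies_per_event
        eid = ev.event_id or f"ev{e_idx}"
        age_subs = ev.age * scale
        if ev.kind == "vertical":
            want = frozenset(ev.clade)
            node = next((n for n, ls in leafset.items() if ls == want), None)
            if node is None:
                raise ValueError(f"no branch with clade {sorted(want)} in tree")
            lo = ages[node]
            hi = ages[node.parent_node] if node.parent_node is not None else np.inf
            if node is root:
                if age_subs < root_age - 1e-12:
                    raise ValueError(
                        f"event {eid}: age {ev.age} below root age; pick an internal branch")
            elif not (lo - 1e-12 <= age_subs <= hi + 1e-12):
                raise ValueError(
                    f"event {eid}: age {ev.age} not on the branch above clade "
                    f"{sorted(want)}")
            _attach(node, age_subs, ev, eid, ncopies)
            vertical_events.append((ev, want, ncopies))
        else:
            for sp in ev.recipients:
                if sp not in leaves:
                    raise ValueError(f"event {eid}: unknown recipient {sp!r}")
                node = leaves[sp]
                hi = ages[node.parent_node]
                if not (0 <= age_subs <= hi + 1e-12):
                    raise ValueError(
                        f"event {eid}: age {ev.age} beyond terminal branch of {sp}")
                _attach(node, age_subs, replace(ev, event_id=eid), f"{eid}.{sp}", ncopies)

    # -- allocate anchors in root coordinates with global spacing -----------
    margin = cfg.min_locus_spacing
    if cfg.genome_length <= 2 * margin:
        raise ValueError("genome_length too small for min_locus_spacing margins")
    taken: list[int] = []
    for plan in plans:
        for _ in range(20000):
            cand = int(rng.integers(margin, cfg.genome_length - margin))
            if all(abs(cand - t) >= cfg.min_locus_spacing for t in taken):
                plan.anchor = cand
                taken.append(cand)
                break
        else:
            raise ValueError(
                "could not place all insertions; increase genome_length or "
                "decrease min_locus_spacing")

    # -- recurse down the tree ----------------------------------------------
    start_age = max([root_age] + [a for evs in per_node.values() for a, _ in evs])
    genome0 = _seq.random_seq_arr(rng, cfg.genome_length, cfg.gc_content)
    results: dict[str, tuple[np.ndarray, list[_Placed]]] = {}

    def _splice(seq: np.ndarray, placed: list[_Placed], plan: _CopyPlan) -> np.ndarray:
        offset = sum(p.added for p in placed if p.anchor < plan.anchor)
        pos = plan.anchor + offset
        te = consensus_arr
        tsd_used = cfg.tsd_length
        if plan.fragment:
            keep = max(1, int(round(plan.retained * te.shape[0])))
            te = te[-keep:] if plan.trunc_side == "left" else te[:keep]
            tsd_used = 0
        new = np.concatenate([seq[:pos + tsd_used], te, seq[pos:]])
        placed.append(_Placed(plan.anchor, te.shape[0] + tsd_used, tsd_used,
                              te.shape[0], plan))
        return new

    def _walk(node, seq: np.ndarray, placed: list[_Placed], from_age: float):
        cur = from_age
        for age, batch in sorted(per_node.get(id(node), []), key=lambda t: -t[0]):
            seq = _evolve_arr(seq, cur - age, cfg.kappa, rng)
            for plan in batch:
                seq = _splice(seq, placed, plan)
            cur = age
        seq = _evolve_arr(seq, cur - ages[node], cfg.kappa, rng)
        if node.is_leaf():
            results[node.taxon.label] = (seq, placed)
        else:
            for child in node.child_nodes():
                _walk(child, seq.copy(), list(placed), ages[node])

    _walk(root, genome0, [], start_age)

    # -- build outputs -------------------------------------------------------
    genomes: dict[str, GenomeRecord] = {}
    rows = []
    for sp in sorted(results):
        seq, placed = results[sp]
        genomes[sp] = GenomeRecord(sp, "chr1", _seq.decode(seq))
        for p in placed:
            offset = sum(q.added for q in placed if q.anchor < p.anchor)
            start = p.anchor + offset + p.tsd_used
            rows.append({
                "species": sp, "seq_id": "chr1",
                "start": start, "end": start + p.te_len, "strand": "+",
                "copy_id": p.plan.copy_id, "event_id": p.plan.event_id,
                "kind": p.plan.kind, "divergence": p.plan.age_subs,
                "fragment": p.plan.fragment, "retained": p.plan.retained,
                "trunc_side": p.plan.trunc_side, "anchor": p.anchor,
            })
    copies_df = pd.DataFrame(rows, columns=[
        "species", "seq_id", "start", "end", "strand", "copy_id", "event_id",
        "kind", "divergence", "fragment", "retained", "trunc_side", "anchor"])

    labels = sorted(leaves)
    pair_counts = {
        (a, b): 0 for i, a in enumerate(labels) for b in labels[i + 1:]}
    for ev, clade, ncopies in vertical_events:
        members = sorted(clade)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pair_counts[(a, b)] += ncopies
    shared_df = pd.DataFrame(
        [{"species_a": a, "species_b": b, "shared_count": c}
         for (a, b), c in sorted(pair_counts.items())],
        columns=["species_a", "species_b", "shared_count"])

    return Scenario(cfg, _seq.decode(consensus_arr), genomes,
                    TruthTable(copies_df, shared_df), scale)


# ---------------------------------------------------------------------------
# canonical scenarios (the package's study conditions)
# ---------------------------------------------------------------------------

DEFAULT_TREE_MYA = "((A:25,B:25):25,(C:25,D:25):25);"
DEFAULT_RATE = 0.002       # substitutions/site/MY
TWO_SPECIES_TREE_MYA = "(A:25,B:25);"


def vertical_scenario(seed: int = 0, *, insert_age: float = 55.0,
                      copies: int | None = None, **overrides) -> Scenario:
    """TE inserted above the root of a 4-species tree; pure vertical descent."""
    cfg = SimConfig(
        species_tree=DEFAULT_TREE_MYA, units="mya", rate=DEFAULT_RATE,
        events=[InsertionEvent("vertical", insert_age,
                               clade=("A", "B", "C", "D"), copies=copies,
                               event_id="root_insertion")],
        seed=seed, **overrides)
    return simulate_scenario(cfg)


def htt_scenario(seed: int = 0, *, recipients: tuple[str, ...] = ("A", "C"),
                 transfer_age: float = 2.0, copies: int | None = None,
                 **overrides) -> Scenario:
    """Recent horizontal transfer into non-sister species; no vertical copies."""
    cfg = SimConfig(
        species_tree=DEFAULT_TREE_MYA, units="mya", rate=DEFAULT_RATE,
        events=[InsertionEvent("horizontal", transfer_age,
                               recipients=recipients, copies=copies,
                               event_id="htt")],
        seed=seed, **overrides)
    return simulate_scenario(cfg)


def htt_discordance_scenario(seed: int = 0, *, transfer_age: float = 2.0,
                             **overrides) -> Scenario:
    """Old vertical background in all species plus a recent transfer between
    non-sisters A and C — the configuration that makes the TE tree contradict
    the species tree."""
    cfg = SimConfig(
        species_tree=DEFAULT_TREE_MYA, units="mya", rate=DEFAULT_RATE,
        events=[
            InsertionEvent("vertical", 55.0, clade=("A", "B", "C", "D"),
                           event_id="root_insertion"),
            InsertionEvent("horizontal", transfer_age, recipients=("A", "C"),
                           event_id="htt"),
        ],
        seed=seed, **overrides)
    return simulate_scenario(cfg)


def presence_absence_scenario(seed: int = 0, *, n_ancestral: int = 10,
                              n_independent: int = 10, **overrides) -> Scenario:
    """Two species sharing ``n_ancestral`` pre-split insertions, each with
    ``n_independent`` private post-split insertions; no fragmentation."""
    overrides.setdefault("genome_length", 250_000)
    overrides.setdefault("fragment_prob", 0.0)
    cfg = SimConfig(
        species_tree=TWO_SPECIES_TREE_MYA, units="mya", rate=DEFAULT_RATE,
        events=[
            InsertionEvent("vertical", 30.0, clade=("A", "B"),
                           copies=n_ancestral, event_id="ancestral"),
            InsertionEvent("horizontal", 5.0, recipients=("A",),
                           copies=n_independent, event_id="post_split_A"),
            InsertionEvent("horizontal", 5.0, recipients=("B",),
                           copies=n_independent, event_id="post_split_B"),
        ],
        seed=seed, **overrides)
    return simulate_scenario(cfg)
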