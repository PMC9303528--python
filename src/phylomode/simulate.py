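"""Synthetic gene-family evolution with known ground truth.

The generator emulates the statistical structure the comparative inference
assumes: each family is gained once on the species tree, lost independently
and heritably along branches, duplicated at designated ancestral nodes, and
observed either through a genome (reliable presence) or a transcriptome
(Bernoulli detection, yielding the *partial* evidence state). From the
simulated histories it can emit the full input bundle of the pipeline —
BLAST-tabular hit tables realizing a planted-block similarity graph, FASTA,
Newick gene trees, an occupancy table and a ground-truth ledger — and score
how well the pipeline recovers the planted truth.

Sequence content is deliberately not simulated: the clustering consumes a
similarity graph, so hit tables are generated directly from the family
structure (strong within-family weights, sparse weak noise edges between
families).

All randomness flows from the single config seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .duplications import DuplicationEvent
from .modes import TraitAnnotation, classify_hg
from .occupancy import ABSENT, PARTIAL, PRESENT, SpeciesCatalog, SpeciesInfo
from .origins import OriginCall
from .species_tree import BACKBONE_NEWICK, Node, SpeciesTree

__all__ = [
    "SimulationConfig",
    "TrueHistory",
    "SimulationResult",
    "simulate_histories",
    "emit_synthetic_inputs",
    "recovery_report",
    "default_trait",
    "true_mode_labels",
]

#: named clades over which family gains are drawn by default
CLADE_GAINS = (
    "Viridiplantae",
    "Streptophyta",
    "Embryophyta",
    "Tracheophyta",
    "Euphyllophyta",
    "Spermatophyta",
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Study conditions for one simulation run.

    Defaults mirror the sampling regime the inference is built for: gains
    spread uniformly over the six named plant clades, a 10% per-branch loss
    probability, duplications planted at Euphyllophyta and Spermatophyta
    with probability 0.3 each, and three transcriptome-only lineages
    (charophyte, hornwort, fern) detected with probability 0.7.
    """

    seed: int = 42
    n_families: int = 100
    newick: str = BACKBONE_NEWICK
    gain_node_distribution: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 / len(CLADE_GAINS) for c in CLADE_GAINS}
    )
    loss_prob: float = 0.1
    dup_prob: Mapping[str, float] = field(
        default_factory=lambda: {"Euphyllophyta": 0.3, "Spermatophyta": 0.3}
    )
    transcriptome_detection: Mapping[str, float] = field(
        default_factory=lambda: {"CHA": 0.7, "HORN": 0.7, "FERN": 0.7}
    )
    within_weight_mean: float = 50.0
    within_weight_sd: float = 5.0
    noise_edge_rate: float = 0.1  # expected cross-family edges per family

    def __post_init__(self):
        if not (0.0 <= self.loss_prob < 1.0):
            raise ValueError("loss_prob must be in [0, 1)")
        total = sum(self.gain_node_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("gain_node_distribution must sum to 1")
        for p in itertools.chain(
            self.dup_prob.values(), self.transcriptome_detection.values()
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        self._tree = SpeciesTree.from_newick(self.newick)
        for label in itertools.chain(
            self.gain_node_distribution, self.dup_prob, self.transcriptome_detection
        ):
            self._tree.node(label)  # KeyError on unknown labels

    @property
    def tree(self) -> SpeciesTree:
        return self._tree

    def catalog(self) -> SpeciesCatalog:
        return SpeciesCatalog(
            SpeciesInfo(
                code=tip,
                name=tip,
                source=(
                    "transcriptome" if tip in self.transcriptome_detection else "genome"
                ),
            )
            for tip in self._tree.tips
        )


@dataclass
class TrueHistory:
    """Planted truth for one family."""

    family_id: str
    gain_node: str
    loss_branches: tuple[str, ...]  # child-node identifier of each lost edge
    dup_nodes: tuple[str, ...]
    surviving_tips: tuple[str, ...]
    occupancy_row: dict[str, int]  # post-detection, the row the pipeline sees
    copy_counts: dict[str, int]
    gene_tree_newick: str | None
    leaves: tuple[str, ...]


@dataclass
class SimulationResult:
    histories: list[TrueHistory]
    config: SimulationConfig
    n_resampled: int
    edges_at_risk: int
    n_losses: int

    def occupancy(self) -> pd.DataFrame:
        tips = self.config.tree.tips
        data = {
            h.family_id: [h.occupancy_row[t] for t in tips] for h in self.histories
        }
        return pd.DataFrame.from_dict(
            data, orient="index", columns=tips, dtype="int8"
        )


def _node_id(node: Node) -> str:
    return node.label if node.label is not None else str(node.index)


def simulate_histories(config: SimulationConfig) -> SimulationResult:
    """Draw ``n_families`` single-gain histories on the species tree.

    Losses are heritable (a lost lineage stays lost); a family extinct
    below its gain node is resampled and counted. Detection failures at
    transcriptome tips downgrade surviving copies to absent in the emitted
    occupancy row (successful detection yields the partial state).
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    gain_labels = sorted(config.gain_node_distribution)
    gain_probs = np.array([config.gain_node_distribution[g] for g in gain_labels])
    dup_labels = sorted(config.dup_prob)

    histories: list[TrueHistory] = []
    n_resampled = 0
    edges_at_risk = 0
    n_losses = 0
    for idx in range(config.n_families):
        fam = f"F{idx + 1:04d}"
        for _attempt in range(10_000):
            gain_label = gain_labels[rng.choice(len(gain_labels), p=gain_probs)]
            gain = tree.node(gain_label)
            alive_nodes: set[int] = {gain.index}
            losses: list[str] = []
            at_risk = 0
            stack = [gain]
            while stack:
                node = stack.pop()
                for child in node.children:
                    at_risk += 1
                    if rng.random() < config.loss_prob:
                        losses.append(_node_id(child))
                    else:
                        alive_nodes.add(child.index)
                        stack.append(child)
            survivors = tuple(
                t for t in tree.tips if tree.node(t).index in alive_nodes
            )
            if survivors:
                break
            n_resampled += 1
        else:  # pragma: no cover - loss_prob < 1 guarantees progress
            raise RuntimeError("family resampling did not terminate")
        edges_at_risk += at_risk
        n_losses += len(losses)

        dup_nodes = []
        for label in dup_labels:
            node = tree.node(label)
            observable = (
                node.index in alive_nodes
                and tree.is_ancestor(gain, node, strict=False)
                and any(t in node.tip_set for t in survivors)
            )
            if observable and rng.random() < config.dup_prob[label]:
                dup_nodes.append(label)

        row: dict[str, int] = {}
        for tip in tree.tips:
            if tip not in survivors:
                row[tip] = ABSENT
            elif tip in config.transcriptome_detection:
                detected = rng.random() < config.transcriptome_detection[tip]
                row[tip] = PARTIAL if detected else ABSENT
            else:
                row[tip] = PRESENT
        detected_tips = {t for t in survivors if row[t] != ABSENT}
        newick, leaves = _build_gene_tree(fam, gain, detected_tips, set(dup_nodes))
        copy_counts: dict[str, int] = {}
        for name in leaves:
            sp = name.split("|", 1)[0]
            copy_counts[sp] = copy_counts.get(sp, 0) + 1
        histories.append(
            TrueHistory(
                family_id=fam,
                gain_node=gain_label,
                loss_branches=tuple(losses),
                dup_nodes=tuple(dup_nodes),
                surviving_tips=survivors,
                occupancy_row=row,
                copy_counts=copy_counts,
                gene_tree_newick=newick,
                leaves=tuple(leaves),
            )
        )
    return SimulationResult(
        histories=histories,
        config=config,
        n_resampled=n_resampled,
        edges_at_risk=edges_at_risk,
        n_losses=n_losses,
    )


def _build_gene_tree(
    fam: str, gain: Node, alive_tips: set[str], dup_nodes: set[str]
) -> tuple[str | None, list[str]]:
    """Topology-true gene tree over the detected tips.

    A duplication at node N splits the lineage into two copies spanning N's
    subtree; remaining deeper planted duplications continue in the first
    copy only, so every planted event appears exactly once in the tree.
    Returns (newick or None if < 2 leaves, leaf names).
    """
    counter = itertools.count(1)
    leaves: list[str] = []

    def at(node: Node, pending: frozenset[str]):
        if node.label is not None and node.label in pending:
            rest = pending - {node.label}
            first = below(node, rest)
            second = below(node, frozenset())
            parts = [p for p in (first, second) if p is not None]
            if len(parts) == 2:
                return f"({parts[0]},{parts[1]})"
            return parts[0] if parts else None
        return below(node, pending)

    def below(node: Node, pending: frozenset[str]):
        if node.is_tip:
            if node.label not in alive_tips:
                return None
            name = f"{node.label}|{fam}_{next(counter)}"
            leaves.append(name)
            return name
        parts = [p for p in (at(c, pending) for c in node.children) if p is not None]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    newick = at(gain, frozenset(dup_nodes))
    if newick is None or len(leaves) < 2:
        return None, leaves
    return newick + ";", leaves


# --------------------------------------------------------------------- emit
def emit_synthetic_inputs(result: SimulationResult, outdir: str | Path) -> Path:
    """Write the pipeline's input bundle for a simulated cohort.

    Produces ``hits.tsv`` (outfmt-6; reciprocal within-family hits with
    strong weights plus Poisson cross-family noise edges), ``proteins.fasta``,
    per-family Newick gene trees under ``genetrees/``, ``occupancy.tsv``,
    ``catalog.yaml`` and the ground-truth ledger ``truth.json``. Re-running
    with the same config yields a byte-identical bundle.
    """
    if not result.histories:
        raise ValueError("no histories to emit")
    config = result.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 17])

    # FASTA (ids only matter; short random peptides)
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    all_leaves: list[tuple[str, str]] = []  # (protein, family)
    for h in result.histories:
        for name in h.leaves:
            all_leaves.append((name, h.family_id))
            seq = "M" + "".join(rng.choice(_AA, size=19))
            records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(outdir / "proteins.fasta"), "fasta")

    # hit table
    with open(outdir / "hits.tsv", "w") as fh:
        def write_hit(a: str, b: str, w: float) -> None:
            evalue = 10.0 ** (-w)
            fh.write(
                f"{a}\t{b}\t90.0\t100\t10\t0\t1\t100\t1\t100\t"
                f"{evalue:.3e}\t{2 * w:.1f}\n"
            )

        for h in result.histories:
            for name in h.leaves:
                write_hit(name, name, 200.0)
            for a, b in itertools.combinations(h.leaves, 2):
                w = float(
                    np.clip(
                        rng.normal(config.within_weight_mean, config.within_weight_sd),
                        5.0,
                        200.0,
                    )
                )
                write_hit(a, b, w)
                write_hit(b, a, w)
        n_noise = int(rng.poisson(config.noise_edge_rate * len(result.histories)))
        if n_noise and len(result.histories) > 1:
            for _ in range(n_noise):
                i, j = rng.choice(len(all_leaves), size=2, replace=False)
                if all_leaves[i][1] == all_leaves[j][1]:
                    continue  # only cross-family noise
                w = float(np.clip(rng.normal(1.0, 0.2), 0.1, 3.0))
                write_hit(all_leaves[i][0], all_leaves[j][0], w)

    gt_dir = outdir / "genetrees"
    gt_dir.mkdir(exist_ok=True)
    for h in result.histories:
        if h.gene_tree_newick is not None:
            (gt_dir / f"{h.family_id}.nwk").write_text(h.gene_tree_newick + "\n")

    result.occupancy().to_csv(outdir / "occupancy.tsv", sep="\t", index_label="hg_id")
    config.catalog().to_yaml(str(outdir / "catalog.yaml"))

    ledger = {
        "stats": {
            "n_families": len(result.histories),
            "n_resampled": result.n_resampled,
            "edges_at_risk": result.edges_at_risk,
            "n_losses": result.n_losses,
        },
        "families": {
            h.family_id: {
                "gain_node": h.gain_node,
                "loss_branches": list(h.loss_branches),
                "dup_nodes": list(h.dup_nodes),
                "copy_counts": h.copy_counts,
            }
            for h in result.histories
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir


# ------------------------------------------------------------------- scoring
def default_trait(config: SimulationConfig) -> TraitAnnotation:
    """Trait annotation used to score mode classification on simulations:
    a land-plant innovation whose expansion nodes are the planted
    duplication nodes."""
    return TraitAnnotation(
        name="synthetic_innovation",
        origin_node="Embryophyta",
        expansion_nodes=tuple(sorted(config.dup_prob)),
        gene_ids=("synthetic",),
    )


def true_mode_labels(
    history: TrueHistory,
    trait: TraitAnnotation,
    config: SimulationConfig,
    retention_threshold: float = 1.0,
) -> frozenset[str]:
    """Mode labels implied by the planted truth (not by inference)."""
    tree = config.tree
    gain = tree.node(history.gain_node)
    ideal_row = {
        t: (
            ABSENT
            if t not in history.surviving_tips
            else (PARTIAL if t in config.transcriptome_detection else PRESENT)
        )
        for t in tree.tips
    }
    origin = OriginCall(
        hg_id=history.family_id,
        origin=gain,
        origin_label=history.gain_node,
        implied_losses=0,
        presence_tips=frozenset(history.surviving_tips),
    )
    events = [
        DuplicationEvent(
            leafset=frozenset(),
            mapped_node=tree.node(lbl),
            mapped_label=lbl,
        )
        for lbl in history.dup_nodes
    ]
    call = classify_hg(
        origin, events, trait, ideal_row, tree, config.catalog(),
        retention_threshold=retention_threshold,
    )
    return call.labels


def recovery_report(
    histories: Sequence[TrueHistory],
    calls: Mapping[str, object],
) -> dict:
    """Score pipeline output against the planted truth.

    ``calls`` is the mapping produced by
    :func:`phylomode.pipeline.analyze_simulation`: keys ``origins``
    (family -> origin label or None), ``dup_nodes`` (family -> set of
    mapped labels), optionally ``modes`` (family -> label frozenset) with
    ``true_modes``, and optionally ``cluster_assignment`` (protein ->
    cluster id) for clustering agreement.

    Returns a dict with origin exact-recovery rate, duplication-node
    precision and recall, a mode-label confusion table and (if clusters
    were supplied) the adjusted Rand index against the planted families.
    Unknown family ids in the calls are fatal.
    """
    truth = {h.family_id: h for h in histories}
    origins: Mapping[str, str | None] = calls.get("origins", {})
    unknown = set(origins) - set(truth)
    if unknown:
        raise KeyError(f"calls reference unknown families: {sorted(unknown)[:5]}")

    called = {f: o for f, o in origins.items() if o is not None}
    n_correct = sum(1 for f, o in called.items() if o == truth[f].gain_node)
    report: dict = {
        "n_families": len(truth),
        "n_origin_called": len(called),
        "origin_recovery": (n_correct / len(called)) if called else float("nan"),
    }

    dup_calls: Mapping[str, set] = calls.get("dup_nodes", {})
    if set(dup_calls) - set(truth):
        raise KeyError("duplication calls reference unknown families")
    tp = fp = fn = 0
    for fam, h in truth.items():
        true_set = set(h.dup_nodes)
        pred_set = set(dup_calls.get(fam, ()))
        tp += len(true_set & pred_set)
        fp += len(pred_set - true_set)
        fn += len(true_set - pred_set)
    report["dup_recall"] = tp / (tp + fn) if (tp + fn) else float("nan")
    report["dup_precision"] = tp / (tp + fp) if (tp + fp) else float("nan")

    if "modes" in calls and "true_modes" in calls:
        pred = calls["modes"]
        true = calls["true_modes"]
        fams = sorted(set(pred) & set(true))
        labels_true = ["+".join(sorted(true[f])) or "none" for f in fams]
        labels_pred = ["+".join(sorted(pred[f])) or "none" for f in fams]
        report["mode_confusion"] = pd.crosstab(
            pd.Series(labels_true, name="true"),
            pd.Series(labels_pred, name="predicted"),
        )
        report["mode_accuracy"] = (
            sum(t == p for t, p in zip(labels_true, labels_pred)) / len(fams)
            if fams
            else float("nan")
        )

    if "cluster_assignment" in calls:
        assignment: Mapping[str, str] = calls["cluster_assignment"]
        fam_of = {name: h.family_id for h in histories for name in h.leaves}
        proteins = sorted(set(assignment) & set(fam_of))
        report["clustering_ari"] = adjusted_rand_score(
            [fam_of[p] for p in proteins], [assignment[p] for p in proteins]
        )
    return report
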