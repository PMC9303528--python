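"""Species occupancy of homology groups and transcriptome augmentation.

Occupancy is the three-state evidence table behind presence/absence
heatmaps: for each homology group and species the cell is *present* (2)
when the species contributes at least one genome-derived member, *partial*
(1) when the only evidence is transcriptome-derived (reciprocal-best-hit
attached), and *absent* (0) otherwise. Transcriptome assemblies are
incomplete, so their evidence is kept distinguishable from genome evidence
throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .blast import HitRecord, species_of
from .similarity import HomologyGroup

logger = logging.getLogger(__name__)

__all__ = [
    "ABSENT",
    "PARTIAL",
    "PRESENT",
    "SpeciesInfo",
    "SpeciesCatalog",
    "build_occupancy",
    "rbh_augment",
    "query_hgs_by_gene_ids",
]

ABSENT, PARTIAL, PRESENT = 0, 1, 2

_SOURCES = ("genome", "transcriptome")


@dataclass(frozen=True)
class SpeciesInfo:
    code: str
    name: str = ""
    source: str = "genome"
    group: str = ""

    def __post_init__(self):
        if self.source not in _SOURCES:
            raise ValueError(f"{self.code}: source must be one of {_SOURCES}")


class SpeciesCatalog:
    """Registry of sampled species: code, display name, data source, group."""

    def __init__(self, entries: Iterable[SpeciesInfo]):
        self._entries: dict[str, SpeciesInfo] = {}
        for e in entries:
            if e.code in self._entries:
                raise ValueError(f"duplicate species code {e.code!r}")
            self._entries[e.code] = e

    @classmethod
    def from_yaml(cls, path: str) -> "SpeciesCatalog":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            SpeciesInfo(
                code=code,
                name=info.get("name", ""),
                source=info.get("source", "genome"),
                group=info.get("group", ""),
            )
            for code, info in raw.items()
        )

    def to_yaml(self, path: str) -> None:
        data = {
            e.code: {"name": e.name, "source": e.source, "group": e.group}
            for e in self._entries.values()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> SpeciesInfo:
        return self._entries[code]

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def codes(self) -> list[str]:
        return list(self._entries)

    def genome_species(self) -> set[str]:
        return {e.code for e in self if e.source == "genome"}

    def transcriptome_species(self) -> set[str]:
        return {e.code for e in self if e.source == "transcriptome"}


def build_occupancy(
    hgs: Sequence[HomologyGroup], catalog: SpeciesCatalog
) -> pd.DataFrame:
    """Three-state occupancy matrix (rows HGs, columns catalog species).

    present (2) needs >= 1 genome-evidence member from the species; partial
    (1) needs transcriptome evidence only; absent (0) otherwise. Members
    whose species is not in the catalog are a fatal configuration error.
    """
    unknown = sorted(
        {sp for hg in hgs for sp in hg.species if sp not in catalog}
    )
    if unknown:
        raise KeyError(f"member species missing from catalog: {unknown}")
    cols = catalog.codes
    data = pd.DataFrame(
        ABSENT, index=[hg.hg_id for hg in hgs], columns=cols, dtype="int8"
    )
    for hg in hgs:
        for member in hg.members:
            sp = hg.member_species[member]
            state = PRESENT if hg.evidence[member] == "genome" else PARTIAL
            if state > data.at[hg.hg_id, sp]:
                data.at[hg.hg_id, sp] = state
    return data


def _best_hits(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: max bitscore, then alignment length, then
    lexicographically smallest subject id (a deterministic chain even when
    floating-point scores tie)."""
    best: dict[str, HitRecord] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            continue
        key = (hit.bitscore, hit.length, _neg_lex(hit.subject_id))
        cur_key = (cur.bitscore, cur.length, _neg_lex(cur.subject_id))
        if key > cur_key:
            best[hit.query_id] = hit
    return best


class _neg_lex(str):
    """Orders strings reversed so that max() prefers the smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def rbh_augment(
    hg: HomologyGroup,
    forward_hits: Sequence[HitRecord],
    reverse_hits: Sequence[HitRecord],
    max_species: int = 20,
    species_delim: str = "|",
) -> HomologyGroup:
    """Attach transcriptome sequences to an HG by reciprocal best hit.

    ``forward_hits`` are searches of the HG's query genes against one
    transcriptome database; ``reverse_hits`` are the database sequences
    searched back against the query proteome. For each query ``q`` and each
    database species the best forward hit ``d`` is taken (a multi-species
    database contributes one candidate per species per query); ``d`` is
    attached iff the best reverse hit of ``d`` against the whole query
    proteome is ``q``. At most ``max_species`` distinct new species are
    attached per database, keeping the species with the highest best
    forward bitscores. Returns a new HomologyGroup; the input is not
    mutated. Idempotent: reapplying the same tables adds nothing.
    """
    if not forward_hits or not reverse_hits:
        logger.warning("%s: empty RBH hit table(s), group unchanged", hg.hg_id)
        return HomologyGroup(
            hg.hg_id, set(hg.members), dict(hg.member_species), dict(hg.evidence)
        )
    fwd_by_species: dict[str, list[HitRecord]] = {}
    for hit in forward_hits:
        fwd_by_species.setdefault(species_of(hit.subject_id, species_delim), []).append(hit)
    best_rev = _best_hits(reverse_hits)

    # candidate additions: per-species reciprocal pairs seeded by HG queries
    candidates: dict[str, float] = {}  # db sequence -> forward bitscore
    for sp_hits in fwd_by_species.values():
        for q, fwd in _best_hits(sp_hits).items():
            if q not in hg.members:
                continue
            d = fwd.subject_id
            rev = best_rev.get(d)
            if rev is not None and rev.subject_id == q:
                candidates[d] = max(candidates.get(d, 0.0), fwd.bitscore)

    # cap on distinct transcriptome species, best-scoring species first;
    # ranking the full candidate set (not only first-time additions) makes
    # reapplication with the same tables a no-op
    by_species: dict[str, list[tuple[float, str]]] = {}
    for d, score in candidates.items():
        by_species.setdefault(species_of(d, species_delim), []).append((score, d))
    genome_backed = {
        hg.member_species[m] for m in hg.members if hg.evidence[m] == "genome"
    }
    capped_pool = sorted(
        (sp for sp in by_species if sp not in genome_backed),
        key=lambda sp: (-max(s for s, _ in by_species[sp]), sp),
    )
    kept_species = set(capped_pool[:max_species]) | (set(by_species) & genome_backed)

    members = set(hg.members)
    member_species = dict(hg.member_species)
    evidence = dict(hg.evidence)
    for sp in sorted(kept_species):
        for _, d in sorted(by_species[sp], reverse=True):
            if d in members:
                continue
            members.add(d)
            member_species[d] = sp
            evidence[d] = "transcriptome"
    return HomologyGroup(hg.hg_id, members, member_species, evidence)


def query_hgs_by_gene_ids(
    hgs: Sequence[HomologyGroup], id_list: Sequence[str]
) -> dict[str, str | None]:
    """Map query gene ids (e.g. UniProt-style reference-species ids) to HGs.

    Several query ids may share one HG (tandem paralogues like CPC/TRY/ETC1
    cluster together); an id found in more than one HG violates the
    partition invariant and is fatal. Unmatched ids map to ``None`` with a
    warning.
    """
    if not id_list:
        raise ValueError("empty gene id list")
    index: dict[str, str] = {}
    for hg in hgs:
        for member in hg.members:
            if member in index and index[member] != hg.hg_id:
                raise ValueError(
                    f"{member!r} appears in both {index[member]} and {hg.hg_id}: "
                    "homology groups must partition the protein set"
                )
            index[member] = hg.hg_id
    out: dict[str, str | None] = {}
    for gid in id_list:
        hit = index.get(gid)
        if hit is None:
            logger.warning("gene id %s not found in any homology group", gid)
        out[gid] = hit
    return out
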