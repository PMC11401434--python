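"""Conserved-synteny analysis: k-gene neighbor profiles around focal loci,
weighted-Jaccard scoring against paralog-diagnostic marker sets, label
assignment, and cross-species conservation.

Synteny here means conservation of linkage of orthologous loci regardless of
exact gene order or intervening genes, so the window is measured in genes,
not base pairs.  Marker sets distill the neighborhoods that diagnose each
tenascin paralog in jawed vertebrates (e.g. TNC next to TNFSF8/PAPPA1/ASTN2;
TNR next to COP1; TNX next to CYP21/C4/ATF6B; TNW next to MRPS14 and
adjacent, opposite-strand, to TNR).  They are shipped as editable YAML.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import config
from .records import GeneLocus

#: assignment thresholds: below the floor, or inside the margin, -> UNCLASSIFIED
SCORE_FLOOR = 0.15
SCORE_MARGIN = 0.05
ADJACENCY_BONUS = 1.5


@dataclass(frozen=True)
class Neighbor:
    symbol: str
    strand: str
    distance: int  # signed gene-distance from the focal locus (never 0)


@dataclass
class NeighborProfile:
    focal: GeneLocus
    window_k: int
    neighbors: list[Neighbor] = field(default_factory=list)

    def symbols(self) -> set[str]:
        return {n.symbol.upper() for n in self.neighbors}


def _normalize(symbol: str, synonyms: Mapping[str, str]) -> str:
    s = symbol.upper()
    return synonyms.get(s, s)


def neighbor_profile(loci: Sequence[GeneLocus], focal_symbol: str, species: str,
                     k: int = 5, chrom: str | None = None) -> NeighborProfile:
    """The k genes on each side of the focal locus on its chromosome (fewer
    at chromosome ends), sorted by signed gene-distance.  The focal locus
    must be unique among the queried loci; ambiguity raises an error listing
    the candidates (pass ``chrom`` to disambiguate duplicated loci)."""
    pool = [g for g in loci if g.species == species
            and (chrom is None or g.chrom == chrom)]
    focal_hits = [g for g in pool if g.symbol.upper() == focal_symbol.upper()]
    if not focal_hits:
        raise ValueError(f"focal symbol {focal_symbol!r} absent for {species}"
                         + (f" on {chrom}" if chrom else ""))
    if len(focal_hits) > 1:
        cand = ", ".join(f"{g.chrom}:{g.start}-{g.end}" for g in focal_hits)
        raise ValueError(f"focal symbol {focal_symbol!r} ambiguous for "
                         f"{species}: candidates {cand}")
    focal = focal_hits[0]
    chrom_loci = sorted((g for g in pool if g.chrom == focal.chrom),
                        key=lambda g: (g.start, g.end, g.symbol))
    idx = chrom_loci.index(focal)
    neighbors = []
    for i in range(max(0, idx - k), min(len(chrom_loci), idx + k + 1)):
        if i == idx:
            continue
        g = chrom_loci[i]
        neighbors.append(Neighbor(symbol=g.symbol, strand=g.strand,
                                  distance=i - idx))
    neighbors.sort(key=lambda n: n.distance)
    return NeighborProfile(focal=focal, window_k=k, neighbors=neighbors)


def list_focal_loci(loci: Sequence[GeneLocus], focal_symbol: str, species: str
                    ) -> list[GeneLocus]:
    """All occurrences of a focal symbol for a species (one per duplicated
    copy after a WGD)."""
    return [g for g in loci if g.species == species
            and g.symbol.upper() == focal_symbol.upper()]


def synteny_score(profile: NeighborProfile, marker_set: Mapping[str, float],
                  synonyms: Mapping[str, str] | None = None) -> float:
    """Weighted marker recovery in [0, 1].

    Each marker contributes its weight if a synonym-normalized neighbor
    matches; markers sitting immediately adjacent to the focal locus
    (gene-distance 1) count with a 1.5x bonus.  The sum is renormalized by
    the maximum attainable weight (every marker present and adjacent):

        score = sum_present(w*b) / (1.5 * sum_all(w))

    so adjacency keeps discriminating even when two neighborhoods overlap
    (the tandem TNR/TNW arrangement puts both marker sets in one window).
    """
    if synonyms is None:
        synonyms = config.symbol_synonyms()
    by_symbol: dict[str, int] = {}
    for n in profile.neighbors:
        s = _normalize(n.symbol, synonyms)
        dist = abs(n.distance)
        if s not in by_symbol or dist < by_symbol[s]:
            by_symbol[s] = dist
    num = 0.0
    den = ADJACENCY_BONUS * sum(marker_set.values())
    for marker, w in marker_set.items():
        m = _normalize(marker, synonyms)
        if m in by_symbol:
            bonus = ADJACENCY_BONUS if by_symbol[m] == 1 else 1.0
            num += w * bonus
    return num / den if den > 0 else 0.0


def matched_markers(profile: NeighborProfile, marker_set: Mapping[str, float],
                    synonyms: Mapping[str, str] | None = None) -> set[str]:
    """The marker symbols of a set found (synonym-normalized) in a profile."""
    if synonyms is None:
        synonyms = config.symbol_synonyms()
    present = {_normalize(n.symbol, synonyms) for n in profile.neighbors}
    return {m for m in marker_set if _normalize(m, synonyms) in present}


def synteny_assign(profile: NeighborProfile,
                   marker_sets: Mapping[str, Mapping[str, float]] | None = None,
                   synonyms: Mapping[str, str] | None = None,
                   score_floor: float = SCORE_FLOOR,
                   score_margin: float = SCORE_MARGIN
                   ) -> tuple[str, float, Optional[tuple[str, float]]]:
    """Argmax-score label with an UNCLASSIFIED guard: top score below
    ``score_floor`` or within ``score_margin`` of the runner-up."""
    if marker_sets is None:
        marker_sets = config.marker_sets()
    if len(marker_sets) < 2:
        raise ValueError("need at least two marker sets")
    scores = sorted(
        ((label, synteny_score(profile, ms, synonyms))
         for label, ms in marker_sets.items()),
        key=lambda kv: (-kv[1], kv[0]))
    (top_label, top), (ru_label, ru) = scores[0], scores[1]
    runner_up = (ru_label, ru)
    if top < score_floor or top - ru < score_margin:
        return "UNCLASSIFIED", top, runner_up
    return top_label, top, runner_up


def apply_tnw_adjacency(assignments: list[dict],
                        marker_sets: Mapping[str, Mapping[str, float]] | None = None,
                        synonyms: Mapping[str, str] | None = None,
                        score_floor: float = SCORE_FLOOR,
                        score_margin: float = SCORE_MARGIN) -> list[dict]:
    """Joint TNW resolution over a set of per-locus assignments.

    TNW is diagnosed primarily by its local-duplication signature — an
    inverted tandem duplicate sitting immediately adjacent to TNR on the
    opposite strand, next to MRPS14 — not by marker content alone (its
    two-marker set saturates too easily inside the shared TNR/TNW window).
    The procedure:

    1. re-assign every locus by argmax over the non-TNW marker sets;
    2. promote to TNW any locus immediately flanked by MRPS14 on one side
       and by a TNR-assigned locus on the opposite strand on the other;
    3. for loci with no adjacent co-assigned locus (the dispersed,
       coelacanth-style arrangement), assign TNW when the TNW-set score
       clears the floor and beats every other set by the margin.

    ``assignments`` are dicts with keys ``profile`` (NeighborProfile),
    ``label`` and ``score``; they are updated in place and returned.
    """
    if synonyms is None:
        synonyms = config.symbol_synonyms()
    if marker_sets is None:
        marker_sets = config.marker_sets()
    others = {k: v for k, v in marker_sets.items() if k != "TNW"}
    tnw_set = marker_sets.get("TNW", {})

    for a in assignments:
        label, score, runner = synteny_assign(a["profile"], others, synonyms,
                                              score_floor, score_margin)
        a["label"], a["score"], a["runner_up"] = label, score, runner

    focal_index = {
        (a["profile"].focal.species, a["profile"].focal.chrom,
         a["profile"].focal.symbol.upper()): a
        for a in assignments}

    def _adjacent_assigned(prof: NeighborProfile):
        for n in prof.neighbors:
            if abs(n.distance) == 1:
                key = (prof.focal.species, prof.focal.chrom, n.symbol.upper())
                if key in focal_index:
                    yield focal_index[key]

    for a in assignments:
        prof: NeighborProfile = a["profile"]
        # TNW sits *between* TNR and MRPS14, so MRPS14 must be immediately
        # adjacent; this also keeps the true TNR locus (MRPS14 two genes
        # away) from being promoted.
        mrps14_adjacent = any(
            _normalize(n.symbol, synonyms) == "MRPS14" and abs(n.distance) == 1
            for n in prof.neighbors)
        adjacent = list(_adjacent_assigned(prof))
        promoted = False
        if mrps14_adjacent:
            for other in adjacent:
                tnr = other["profile"].focal
                if other["label"] == "TNR" and tnr.strand != prof.focal.strand \
                        and "." not in (tnr.strand, prof.focal.strand):
                    a["label"] = "TNW"
                    a["score"] = synteny_score(prof, tnw_set, synonyms)
                    a["tnw_adjacency_rule"] = True
                    promoted = True
                    break
        # Standalone (dispersed) TNW: only when the locus carries no adjacent
        # co-assigned tenascin and no adjacent COP1.  COP1 adjacency is the
        # TNR hallmark; a locus flanked by both COP1 and MRPS14 is a TNR
        # whose TNW neighbor was lost, not a TNW.
        cop1_adjacent = any(
            _normalize(n.symbol, synonyms) == "COP1" and abs(n.distance) == 1
            for n in prof.neighbors)
        if not promoted and not adjacent and not cop1_adjacent and tnw_set:
            tnw_score = synteny_score(prof, tnw_set, synonyms)
            best_other = a["score"] if a["label"] != "UNCLASSIFIED" else 0.0
            if tnw_score >= score_floor and tnw_score - best_other >= score_margin:
                a["label"] = "TNW"
                a["score"] = tnw_score
    return assignments


def cross_species_conservation(profiles: Sequence[NeighborProfile],
                               synonyms: Mapping[str, str] | None = None
                               ) -> tuple[list[str], np.ndarray]:
    """Pairwise Jaccard similarity of synonym-normalized neighbor symbol
    sets; rows/columns are labelled by species."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if synonyms is None:
        synonyms = config.symbol_synonyms()
    sets = [{_normalize(n.symbol, synonyms) for n in p.neighbors}
            for p in profiles]
    labels = [p.focal.species for p in profiles]
    n = len(sets)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            m[i, j] = m[j, i] = (len(sets[i] & sets[j]) / len(union)) if union else 0.0
    return labels, m
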