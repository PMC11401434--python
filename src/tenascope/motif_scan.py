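"""Sequence-motif level analyses.

Covers four things the domain grammar alone cannot see:

* integrin-recognition tripeptides (RGD/RGE/KGD and IDG/IEG) positioned by
  FN3 loop windows, plus the ELVIS strand-A motif;
* glutamine-rich K(E/D)QTQST repeat blocks of cyprinid-style TNX;
* the assembly region between signal peptide and first EGF-like domain:
  reference-mapped cysteine conservation, the vFnHvYnINvP / vFtHrIniP
  conserved motifs, and coiled-coil heptad scoring with the RhExLE check;
* position-frequency matrices (the numeric content of a sequence logo).

FN3 loop windows are fractional positions on the domain: the canonical
seven-strand (A-G) beta-sandwich puts the B-C loop around 22-35% of the domain
length, the F-G loop around 70-88%, and strand A in the first 12%.  The
windows are this module's calibration of that topology and are configurable.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import Architecture, DomainAnnotation, DomainKind, ProteinRecord

#: fractional (start, end) windows on an FN3 domain, rounded outward
LOOP_WINDOWS = {
    "BC": (0.22, 0.35),
    "FG": (0.70, 0.88),
    "STRAND_A": (0.0, 0.12),
}

#: which tripeptides belong to which loop
FG_MOTIFS = ("RGD", "RGE", "KGD")
BC_MOTIFS = ("IDG", "IEG")
STRAND_A_MOTIFS = ("ELVIS",)

#: hydrophobic set for heptad a/d positions
HEPTAD_HYDROPHOBIC = frozenset("AILMFV")

RHEXLE_RE = re.compile("R[AILMFV]E.LE")

CONSERVED_ASSEMBLY_MOTIFS = ("vFnHvYnINvP", "vFtHrIniP")


@dataclass(frozen=True)
class IntegrinMotifHit:
    protein_id: str
    fn3_index: int          # 1-based, N->C order
    motif: str
    loop: str               # FG | BC | STRAND_A
    position: int           # 1-based residue index in the protein


@dataclass(frozen=True)
class RepeatBlock:
    protein_id: str
    start: int
    end: int
    n_units: int
    unit_length_mean: float
    motif_positions: tuple[int, ...]


@dataclass
class HeptadAnnotation:
    start: int
    end: int
    register_offset: int    # 0..6; offset 0 puts the window's first residue at 'a'
    score: float
    rhexle_present: bool


@dataclass
class AssemblyProfile:
    protein_id: str
    region: tuple[int, int]
    cysteines: dict[int, bool]          # reference position -> conserved in query
    heptad: Optional[HeptadAnnotation]
    rhexle_present: bool
    conserved_motif_hits: list[dict] = field(default_factory=list)


@dataclass
class PositionFrequencyMatrix:
    columns: list[dict[str, float]]     # residue (or '-') -> frequency
    n_seqs: int
    information_content: list[float]    # bits, gaps excluded from the entropy
    gap_fractions: list[float]


# ------------------------------------------------------------ loop windows

def fn3_loop_window(loop: str, length: int) -> tuple[int, int]:
    """1-based inclusive window on a domain of ``length`` residues, rounded
    outward (floor on the lower bound, ceil on the upper)."""
    lo_f, hi_f = LOOP_WINDOWS[loop]
    lo = max(1, math.floor(lo_f * length))
    hi = min(length, math.ceil(hi_f * length))
    return lo, hi


def find_integrin_motifs(arch: Architecture, seq: str) -> list[IntegrinMotifHit]:
    """Report each loop-positioned motif occurrence; occurrences of the same
    strings outside their loop windows are deliberately not reported, since
    only exposed-loop copies are candidate integrin ligands."""
    fn3s = sorted(arch.of_kind(DomainKind.FN3), key=lambda d: d.start)
    if not fn3s:
        raise ValueError(f"{arch.protein_id}: architecture has no FN3 domains")
    hits: list[IntegrinMotifHit] = []
    for idx, dom in enumerate(fn3s, start=1):
        domain_seq = seq[dom.start - 1:dom.end]
        L = len(domain_seq)
        for loop, motifs in (("FG", FG_MOTIFS), ("BC", BC_MOTIFS),
                             ("STRAND_A", STRAND_A_MOTIFS)):
            lo, hi = fn3_loop_window(loop, L)
            for motif in motifs:
                start = 0
                while True:
                    pos = domain_seq.find(motif, start)
                    if pos < 0:
                        break
                    p1 = pos + 1  # 1-based within the domain
                    if lo <= p1 <= hi and pos + len(motif) <= L:
                        hits.append(IntegrinMotifHit(
                            protein_id=arch.protein_id, fn3_index=idx,
                            motif=motif, loop=loop,
                            position=dom.start + pos))
                    start = pos + 1
    hits.sort(key=lambda h: (h.position, h.motif))
    return hits


# ------------------------------------------------------------ repeat blocks

def _parse_motif_pattern(pattern: str) -> list[frozenset[str]]:
    """Parse a pattern like ``K[ED]QTQST`` into per-position residue sets."""
    out: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            out.append(frozenset(pattern[i + 1:j]))
            i = j + 1
        else:
            out.append(frozenset(pattern[i]))
            i += 1
    return out


def _motif_instances(seq: str, positions: list[frozenset[str]],
                     max_mismatch: int) -> list[int]:
    """0-based start indices where the pattern matches with at most
    ``max_mismatch`` substitutions."""
    m = len(positions)
    starts = []
    for i in range(len(seq) - m + 1):
        mism = 0
        for k, allowed in enumerate(positions):
            if seq[i + k] not in allowed:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            starts.append(i)
    return starts


def detect_repeats(record: ProteinRecord, motif_pattern: str = "K[ED]QTQST",
                   period_range: tuple[int, int] = (55, 85),
                   max_mismatch: int = 1) -> list[RepeatBlock]:
    """Find tandem repeat blocks marked by a short motif: motif instances
    whose successive spacings fall within ``period_range`` are chained;
    chains of fewer than two units are suppressed."""
    positions = _parse_motif_pattern(motif_pattern)
    starts = _motif_instances(record.seq, positions, max_mismatch)
    lo, hi = period_range
    blocks: list[RepeatBlock] = []
    chain: list[int] = []

    def _close():
        if len(chain) >= 2:
            spacings = [b - a for a, b in zip(chain, chain[1:])]
            blocks.append(RepeatBlock(
                protein_id=record.id,
                start=chain[0] + 1,
                end=chain[-1] + len(positions),
                n_units=len(chain),
                unit_length_mean=sum(spacings) / len(spacings),
                motif_positions=tuple(p + 1 for p in chain)))
        chain.clear()

    for s in starts:
        if not chain:
            chain.append(s)
            continue
        gap = s - chain[-1]
        if lo <= gap <= hi:
            chain.append(s)
        elif gap < lo:
            continue  # near-duplicate mismatch variant inside the same unit
        else:
            _close()
            chain.append(s)
    _close()
    return blocks


# ------------------------------------------------------------ assembly region

def assembly_region(arch: Architecture) -> tuple[int, int]:
    """Region between the signal peptide and the first EGF-like domain."""
    egfs = arch.of_kind(DomainKind.EGF_TN)
    if not egfs:
        raise ValueError(f"{arch.protein_id}: no EGF-like domain, "
                         "assembly region is undefined")
    first_egf = min(d.start for d in egfs)
    sigs = arch.of_kind(DomainKind.SIGNAL)
    start = (max(d.end for d in sigs) + 1) if sigs else 1
    if start >= first_egf:
        raise ValueError(f"{arch.protein_id}: empty assembly region")
    return start, first_egf - 1


def find_conserved_motifs(seq: str, patterns: Sequence[str] = CONSERVED_ASSEMBLY_MOTIFS,
                          max_mismatch: int = 2) -> list[dict]:
    """Search for the mixed-case conserved assembly motifs.  Upper-case
    pattern positions (highly conserved) must match exactly; lower-case
    positions (most-frequent residue) tolerate up to ``max_mismatch``
    substitutions in total."""
    hits = []
    for pattern in patterns:
        m = len(pattern)
        for i in range(len(seq) - m + 1):
            window = seq[i:i + m]
            mism = 0
            ok = True
            for ch, q in zip(pattern, window):
                if ch.isupper():
                    if q != ch:
                        ok = False
                        break
                elif q != ch.upper():
                    mism += 1
                    if mism > max_mismatch:
                        ok = False
                        break
            if ok:
                hits.append({"pattern": pattern, "position": i + 1,
                             "match": window, "mismatches": mism})
    return hits


def detect_heptads(record: ProteinRecord, region: tuple[int, int],
                   min_len: int = 21, max_len: int = 35,
                   min_score: float = 0.6) -> HeptadAnnotation | None:
    """Scan a region for a coiled-coil-like heptad window.

    Over all 7 register offsets and window lengths ``min_len..max_len``, the
    score is the fraction of 'a' and 'd' positions occupied by hydrophobic
    residues (A,I,L,M,F,V).  The maximal-scoring window is reported if its
    score reaches ``min_score``; ties break leftmost, then longest.
    """
    lo, hi = region
    sub = record.seq[lo - 1:hi]
    if len(sub) < min_len:
        return None
    best: HeptadAnnotation | None = None
    for start in range(0, len(sub) - min_len + 1):
        for length in range(min_len, min(max_len, len(sub) - start) + 1):
            window = sub[start:start + length]
            for offset in range(7):
                ad = [window[i] for i in range(length)
                      if (i + offset) % 7 in (0, 3)]
                if not ad:
                    continue
                score = sum(c in HEPTAD_HYDROPHOBIC for c in ad) / len(ad)
                if score < min_score:
                    continue
                cand = HeptadAnnotation(
                    start=lo + start, end=lo + start + length - 1,
                    register_offset=offset, score=score,
                    rhexle_present=bool(RHEXLE_RE.search(window)))
                if (best is None
                        or score > best.score
                        or (score == best.score and
                            (cand.start, -(cand.end - cand.start)) <
                            (best.start, -(best.end - best.start)))):
                    best = cand
    return best


def profile_assembly_region(record: ProteinRecord, arch: Architecture,
                            reference: ProteinRecord,
                            reference_region: tuple[int, int] | None = None,
                            cys_positions: Sequence[int] = (64, 111, 113, 140, 146, 147),
                            ) -> AssemblyProfile:
    """Profile the query's assembly region against a numbering reference
    (human-TNC-style by convention).

    The query region is globally aligned to the reference region; a reference
    cysteine position counts as conserved iff the query column aligned to it
    is a cysteine.  Also reports heptad window, RhExLE and conserved-motif
    hits within the query region.
    """
    from .phylo import global_align
    from .domain_scan import detect_signal_peptide, scan_egf_tenascin, build_architecture

    q_start, q_end = assembly_region(arch)
    if reference_region is None:
        ref_anns = []
        sig = detect_signal_peptide(reference)
        if sig:
            ref_anns.append(sig)
        ref_anns += scan_egf_tenascin(reference, mode="strict")
        reference_region = assembly_region(build_architecture(reference, ref_anns))
    r_start, r_end = reference_region

    aln = global_align(record.seq[q_start - 1:q_end], reference.seq[r_start - 1:r_end])
    # column map: reference absolute position -> aligned query character
    ref_pos = r_start - 1
    by_ref_pos: dict[int, str] = {}
    for qc, rc in zip(aln.aligned_a, aln.aligned_b):
        if rc != "-":
            ref_pos += 1
            by_ref_pos[ref_pos] = qc
    cys = {p: by_ref_pos.get(p, "-") == "C" for p in cys_positions}

    region_seq = record.seq[q_start - 1:q_end]
    motif_hits = find_conserved_motifs(region_seq)
    for h in motif_hits:
        h["position"] += q_start - 1  # to absolute coordinates
    heptad = detect_heptads(record, (q_start, q_end))
    return AssemblyProfile(
        protein_id=record.id, region=(q_start, q_end), cysteines=cys,
        heptad=heptad,
        rhexle_present=bool(heptad and heptad.rhexle_present),
        conserved_motif_hits=motif_hits)


# ------------------------------------------------------------ PFM

def position_frequencies(aligned_seqs: Sequence[str], gap_char: str = "-"
                         ) -> PositionFrequencyMatrix:
    """Per-column residue frequencies (gap included) and information content
    in bits: log2(20) minus the entropy of the gap-excluded residue
    distribution; the gap fraction is reported separately."""
    if not aligned_seqs:
        raise ValueError("no sequences")
    n = len(aligned_seqs[0])
    if any(len(s) != n for s in aligned_seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    n_seqs = len(aligned_seqs)
    columns, ics, gaps = [], [], []
    for j in range(n):
        counts: dict[str, int] = {}
        for s in aligned_seqs:
            counts[s[j]] = counts.get(s[j], 0) + 1
        freqs = {c: k / n_seqs for c, k in sorted(counts.items())}
        columns.append(freqs)
        gap_frac = freqs.get(gap_char, 0.0)
        gaps.append(gap_frac)
        residue_total = n_seqs - counts.get(gap_char, 0)
        if residue_total == 0:
            ics.append(0.0)
            continue
        entropy = 0.0
        for c, k in counts.items():
            if c == gap_char:
                continue
            p = k / residue_total
            entropy -= p * math.log2(p)
        ics.append(math.log2(20) - entropy)
    return PositionFrequencyMatrix(columns=columns, n_seqs=n_seqs,
                                   information_content=ics, gap_fractions=gaps)
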