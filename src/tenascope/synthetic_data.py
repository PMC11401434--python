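"""Fully labelled synthetic inputs for every pipeline stage.

The generator emulates the study conditions the pipeline is built for:

* proteomes whose tenascins follow the family grammar — signal peptide,
  assembly region (reference-style cysteines, heptad window with RhExLE;
  degenerate and short for TNX, mirroring tetrapod TNX), tandem
  tenascin-type EGF-like domains drawn from the consensus grammar, FN3
  arrays from exemplar templates with integrin motifs planted in loop
  windows, and a carboxy-terminal FReD drawn from a labelled template pool;
* decoy proteins that mimic the real false-positive surface: teneurin-like
  EGF-only proteins, FACIT-collagen-like FN3 strings, short signal+FReD
  proteins, and random sequence;
* sequence families evolved along a known tree by per-site substitution
  (no indels by default, keeping the pairwise p-distance in closed form);
* gene-order tables with paralog-specific marker neighborhoods, optional
  whole-genome duplication with per-gene duplicate loss, and the
  TNR->TNW local-duplication signature (adjacent, opposite strand).

Default domain counts follow the canonical paralog architectures: TNR with
four EGF-like and nine FN3 domains, a TNC-style 14x11, a compact TNW (4x5)
and a "classic" TNX (3x5).  Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from ._exemplars import (
    ASSEMBLY_CONSTRAINED,
    ASSEMBLY_CYS_POSITIONS,
    ASSEMBLY_TEMPLATE,
    FN3_EXEMPLARS,
    FRED_TEMPLATES,
    SIGNAL_TEMPLATE,
    TNX_ASSEMBLY_TEMPLATE,
)
from .domain_scan import DEFAULT_EGF_CONSENSUS
from .motif_scan import fn3_loop_window
from .records import (
    AnnotationMethod,
    DomainAnnotation,
    DomainKind,
    GeneLocus,
    ProteinRecord,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_C = "ADEFGHIKLMNPQRSTVWY"

DECOY_KINDS = ("TENEURIN_LIKE", "FN3_STRING", "FRED_ONLY", "RANDOM")


# ------------------------------------------------------------ configuration

@dataclass
class GenomeConfig:
    n_chromosomes: int = 4
    genes_per_chromosome: int = 30
    window_k: int = 5
    gene_loss_rate: float = 0.0
    wgd: bool = False
    local_dup: bool = True

    def __post_init__(self):
        if not 0.0 <= self.gene_loss_rate <= 1.0:
            raise ValueError("gene_loss_rate must be in [0,1]")


def _default_motif_rules() -> dict:
    # TNC carries RGD (F-G loop) and IDG (B-C loop) in its third FN3;
    # TNW carries an IDG; TNR and TNX have none.
    return {
        "TNC": [("RGD", 3, "FG"), ("IDG", 3, "BC")],
        "TNR": [],
        "TNW": [("IDG", 2, "BC")],
        "TNX": [],
    }


@dataclass
class GeneratorConfig:
    seed: int
    species: tuple[str, ...] = ("sp1",)
    paralogs: tuple[str, ...] = ("TNC", "TNR", "TNW", "TNX")
    egf_counts: dict = field(default_factory=lambda: {
        "TNC": 14, "TNR": 4, "TNW": 4, "TNX": 3})
    fn3_counts: dict = field(default_factory=lambda: {
        "TNC": 11, "TNR": 9, "TNW": 5, "TNX": 5})
    motif_plant_rules: dict = field(default_factory=_default_motif_rules)
    decoy_counts: dict = field(default_factory=lambda: {
        "TENEURIN_LIKE": 2, "FN3_STRING": 2, "FRED_ONLY": 2, "RANDOM": 2})
    substitution_rate: float = 0.2     # FReD divergence from its label template
    fn3_divergence: float = 0.10
    assembly_divergence: float = 0.10
    genome: GenomeConfig = field(default_factory=GenomeConfig)

    def __post_init__(self):
        for r in (self.substitution_rate, self.fn3_divergence, self.assembly_divergence):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")
        for label in self.paralogs:
            if self.fn3_counts.get(label, 0) < 1:
                raise ValueError(f"{label}: the grammar requires >=1 FN3 domain")
            if self.egf_counts.get(label, 0) < 1:
                raise ValueError(f"{label}: the grammar requires >=1 EGF domain")


@dataclass
class TruthSet:
    proteins: dict = field(default_factory=dict)   # id -> truth dict
    loci: dict = field(default_factory=dict)       # (species, chrom, symbol) -> label
    tree: Optional[str] = None                     # Newick, when a family was evolved


# ------------------------------------------------------------ sequence pieces

def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protected: Sequence[int] = (), alphabet: str = AA_NO_C) -> str:
    """Substitute each unprotected position with probability ``rate``
    (replacement drawn uniformly from the other letters)."""
    protected_set = set(protected)
    s = list(seq)
    hits = rng.random(len(s)) < rate
    for i in np.flatnonzero(hits):
        if i + 1 in protected_set:
            continue
        choices = [a for a in alphabet if a != s[i]]
        s[i] = choices[rng.integers(0, len(choices))]
    return "".join(s)


def make_egf_unit(rng: np.random.Generator, spacer: int | None = None) -> str:
    """One tenascin-type EGF-like domain drawn from the consensus grammar."""
    if spacer is None:
        spacer = int(rng.integers(4, 7))
    if not 4 <= spacer <= DEFAULT_EGF_CONSENSUS.relaxed_max_c3c4:
        raise ValueError(f"spacer {spacer} outside the grammar")
    out = []
    for idx, (cls, lo, _hi) in enumerate(DEFAULT_EGF_CONSENSUS.segments):
        n = spacer if idx == 6 else lo
        if cls == "x":
            out.append("".join(AA_NO_C[i] for i in rng.integers(0, len(AA_NO_C), n)))
        else:
            out.append(cls * n)
    return "".join(out)


def _plant_motif(domain_seq: str, motif: str, loop: str) -> tuple[str, int]:
    """Write a motif into the middle of its loop window; returns the edited
    domain and the 1-based in-domain motif start."""
    lo, hi = fn3_loop_window(loop, len(domain_seq))
    pos = min(lo + (hi - lo) // 2, len(domain_seq) - len(motif) + 1, hi)
    pos = max(pos, lo)
    s = domain_seq[:pos - 1] + motif + domain_seq[pos - 1 + len(motif):]
    return s, pos


def make_tenascin(config: GeneratorConfig, paralog_label: str,
                  rng: np.random.Generator, species: str = "sp1"
                  ) -> tuple[ProteinRecord, dict]:
    """Generate one grammar-complete tenascin with its truth annotations."""
    if paralog_label not in FRED_TEMPLATES:
        raise ValueError(f"unknown paralog label {paralog_label!r}")
    n_egf = config.egf_counts[paralog_label]
    n_fn3 = config.fn3_counts[paralog_label]

    pieces: list[str] = [SIGNAL_TEMPLATE]
    domains: list[DomainAnnotation] = []
    pid = f"{species}_{paralog_label}"

    def _ann(kind, start, end):
        domains.append(DomainAnnotation(protein_id=pid, kind=kind, start=start,
                                        end=end, method=AnnotationMethod.EXTERNAL))

    pos = len(SIGNAL_TEMPLATE)
    _ann(DomainKind.SIGNAL, 1, pos)

    if paralog_label == "TNX":
        assembly = _mutate(TNX_ASSEMBLY_TEMPLATE, config.assembly_divergence, rng,
                           protected=[i + 1 for i, c in enumerate(TNX_ASSEMBLY_TEMPLATE)
                                      if c == "C"])
    else:
        assembly = _mutate(ASSEMBLY_TEMPLATE, config.assembly_divergence, rng,
                           protected=ASSEMBLY_CONSTRAINED)
    pieces.append(assembly)
    pos += len(assembly)

    for _ in range(n_egf):
        unit = make_egf_unit(rng)
        pieces.append(unit)
        _ann(DomainKind.EGF_TN, pos + 1, pos + len(unit))
        pos += len(unit)

    rules = config.motif_plant_rules.get(paralog_label, [])
    motifs_truth: list[dict] = []
    for i in range(n_fn3):
        dom = _mutate(FN3_EXEMPLARS[i % len(FN3_EXEMPLARS)],
                      config.fn3_divergence, rng)
        for motif, fn3_index, loop in rules:
            if fn3_index == i + 1:
                dom, in_dom = _plant_motif(dom, motif, loop)
                motifs_truth.append({"motif": motif, "fn3_index": fn3_index,
                                     "loop": loop, "position": pos + in_dom})
        pieces.append(dom)
        _ann(DomainKind.FN3, pos + 1, pos + len(dom))
        pos += len(dom)

    fred = _mutate(FRED_TEMPLATES[paralog_label], config.substitution_rate, rng)
    pieces.append(fred)
    _ann(DomainKind.FRED, pos + 1, pos + len(fred))
    pos += len(fred)
    pieces.append("GS")

    record = ProteinRecord(id=pid, seq="".join(pieces), species=species)
    truth = {"label": paralog_label, "domains": domains, "motifs": motifs_truth,
             "is_tenascin": True}
    return record, truth


def make_decoy(kind: str, rng: np.random.Generator, record_id: str,
               species: str = "sp1") -> tuple[ProteinRecord, dict]:
    """A protein that must be rejected by the architecture classifier."""
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}")
    if kind == "TENEURIN_LIKE":
        seq = SIGNAL_TEMPLATE + "".join(make_egf_unit(rng) for _ in range(8)) \
            + "".join(AA_NO_C[i] for i in rng.integers(0, len(AA_NO_C), 40))
    elif kind == "FN3_STRING":
        seq = SIGNAL_TEMPLATE + "".join(
            _mutate(FN3_EXEMPLARS[i % len(FN3_EXEMPLARS)], 0.1, rng)
            for i in range(16))
    elif kind == "FRED_ONLY":
        fred = _mutate(FRED_TEMPLATES["TNR"], 0.1, rng)
        seq = (SIGNAL_TEMPLATE + fred)[:239]   # short signal+FReD protein
    else:  # RANDOM
        n = int(rng.integers(300, 501))
        seq = "".join(AA20[i] for i in rng.integers(0, len(AA20), n))
    record = ProteinRecord(id=record_id, seq=seq, species=species)
    return record, {"label": kind, "is_tenascin": False, "domains": [],
                    "motifs": []}


# ------------------------------------------------------------ family evolution

def evolve_family(root_seq: str, tree, substitution_rate: float,
                  rng: np.random.Generator) -> dict[str, str]:
    """Evolve a sequence along a tree: on each branch every site is
    substituted independently with probability rate x branch-length
    (capped at 1), replacement uniform over the other 19 residues.  No
    indels, so pairwise p-distances have a closed-form expectation."""
    if isinstance(tree, str):
        dtree = dendropy.Tree.get(data=tree, schema="newick",
                                  preserve_underscores=True)
    elif hasattr(tree, "_tree"):
        dtree = tree._tree
    else:
        dtree = tree
    leaves: dict[str, str] = {}
    root = dtree.seed_node
    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in sorted(node.child_nodes(),
                            key=lambda c: min(l.taxon.label for l in c.leaf_iter())):
            p = min(1.0, substitution_rate * (child.edge.length or 0.0))
            s = list(seq)
            hits = rng.random(len(s)) < p
            for i in np.flatnonzero(hits):
                choices = [a for a in AA20 if a != s[i]]
                s[i] = choices[rng.integers(0, len(choices))]
            child_seq = "".join(s)
            if child.is_leaf():
                leaves[child.taxon.label] = child_seq
            else:
                stack.append((child, child_seq))
    return leaves


# ------------------------------------------------------------ genomes

#: offset -> (symbol, strand) neighborhood layouts; offsets are gene
#: distances from the focal locus.  "?" offsets are randomized in the window.
_FIXED_NEIGHBORS = {
    "TNC": {-1: "TNFSF8", 1: "PAPPA1", 2: "ASTN2"},
    "TNR": {-1: "COP1", -2: "PAPPA2", -3: "ASTN1"},
    "TNW": {1: "MRPS14", 2: "KIAA0040"},
    "TNX": {1: "CYP21", -1: "C4"},
}
_SCATTER_NEIGHBORS = {
    "TNC": ["TESK", "TRAF2A", "NOTCH1", "B3GALT8"],
    "TNR": ["ATF6A", "CC2D1B"],
    "TNW": [],
    "TNX": ["ATF6B", "NOTCH4", "PSMB"],
}


def make_genome(config: GeneratorConfig, rng: np.random.Generator,
                species: str = "sp1") -> tuple[list[GeneLocus], TruthSet]:
    """Chromosomes of noise genes with one focal tenascin locus per requested
    paralog, surrounded by its marker neighborhood (fixed adjacencies plus
    markers shuffled within the window).  With ``wgd`` every chromosome is
    duplicated and each duplicate gene is then lost independently at
    ``gene_loss_rate``; with ``local_dup`` the TNW focal locus sits
    immediately adjacent to TNR on the opposite strand."""
    g = config.genome
    truth = TruthSet()
    chroms: dict[str, list[tuple[str, str]]] = {}
    counter = 0
    for c in range(1, g.n_chromosomes + 1):
        genes = []
        for _ in range(g.genes_per_chromosome):
            counter += 1
            genes.append((f"G{counter:04d}", "+" if rng.random() < 0.5 else "-"))
        chroms[f"chr{c}"] = genes

    chrom_names = sorted(chroms)
    # TNR and TNW share a chromosome under local duplication
    placement: dict[str, str] = {}
    ci = 0
    for label in config.paralogs:
        if label == "TNW" and g.local_dup and "TNR" in placement:
            placement[label] = placement["TNR"]
            continue
        placement[label] = chrom_names[ci % len(chrom_names)]
        ci += 1

    def _insert_neighborhood(chrom: str, label: str,
                             reserved_offsets: frozenset = frozenset()):
        genes = chroms[chrom]
        center = len(genes) // 2
        genes[center] = (label, "-" if label == "TNW" else "+")
        truth.loci[(species, chrom, label)] = label
        fixed = dict(_FIXED_NEIGHBORS[label])
        for off, sym in fixed.items():
            idx = center + off
            if 0 <= idx < len(genes) and genes[idx][0] not in config.paralogs:
                genes[idx] = (sym, genes[idx][1])
        scatter = list(_SCATTER_NEIGHBORS[label])
        blocked = set(fixed) | set(reserved_offsets) | {0}
        free = [center + off for off in range(-g.window_k, g.window_k + 1)
                if off not in blocked and 0 <= center + off < len(genes)
                and genes[center + off][0].startswith("G")]
        order = rng.permutation(len(free))
        for sym, slot in zip(scatter, (free[i] for i in order)):
            genes[slot] = (sym, genes[slot][1])

    for label in config.paralogs:
        if label == "TNW" and g.local_dup and "TNR" in placement:
            continue  # placed together with TNR below
        tnw_follows = (label == "TNR" and g.local_dup and "TNW" in config.paralogs)
        _insert_neighborhood(placement[label], label,
                             reserved_offsets=frozenset({1, 2, 3}) if tnw_follows
                             else frozenset())
        if tnw_follows:
            chrom = placement["TNR"]
            genes = chroms[chrom]
            center = len(genes) // 2
            genes[center + 1] = ("TNW", "-")   # inverted tandem duplicate
            truth.loci[(species, chrom, "TNW")] = "TNW"
            for off, sym in _FIXED_NEIGHBORS["TNW"].items():
                idx = center + 1 + off
                if 0 <= idx < len(genes) and genes[idx][0].startswith("G"):
                    genes[idx] = (sym, genes[idx][1])

    if g.wgd:
        for chrom in list(chroms):
            dup_name = chrom + "w"
            kept = []
            for sym, strand in chroms[chrom]:
                if rng.random() < g.gene_loss_rate:
                    continue
                kept.append((sym, strand))
                if sym in config.paralogs:
                    truth.loci[(species, dup_name, sym)] = sym
            if kept:
                chroms[dup_name] = kept

    loci: list[GeneLocus] = []
    for chrom in sorted(chroms):
        for i, (sym, strand) in enumerate(chroms[chrom]):
            start = 1 + i * 10_000
            loci.append(GeneLocus(species=species, chrom=chrom, start=start,
                                  end=start + 4_999, strand=strand, symbol=sym))
    return loci, truth


# ------------------------------------------------------------ benchmark bundle

@dataclass
class Benchmark:
    config: GeneratorConfig
    records: list[ProteinRecord]
    loci: list[GeneLocus]
    truth: TruthSet
    references: list[tuple[str, str, str]]


def reference_freds() -> list[tuple[str, str, str]]:
    """The packaged labelled FReD reference set."""
    return [(label, f"ref_{label}", seq) for label, seq in FRED_TEMPLATES.items()]


def make_reference_tnc() -> ProteinRecord:
    """Deterministic numbering-reference protein (TNC-style): signal,
    unmutated assembly template (cysteines at 64/111/113/140/146/147), one
    minimal EGF-like domain, one FN3 exemplar and the TNC FReD template."""
    egf = []
    for idx, (cls, lo, _hi) in enumerate(DEFAULT_EGF_CONSENSUS.segments):
        n = 4 if idx == 6 else lo
        egf.append(("A" * n) if cls == "x" else cls * n)
    seq = (SIGNAL_TEMPLATE + ASSEMBLY_TEMPLATE + "".join(egf)
           + FN3_EXEMPLARS[0] + FRED_TEMPLATES["TNC"] + "GS")
    return ProteinRecord(id="ref_TNC", seq=seq, species="reference")


def make_benchmark(config: GeneratorConfig) -> Benchmark:
    """Proteomes + genomes for every configured species, with decoys and the
    labelled reference FReDs: the standard end-to-end test bed."""
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    truth = TruthSet()
    loci: list[GeneLocus] = []
    for species in config.species:
        for label in config.paralogs:
            rec, t = make_tenascin(config, label, rng, species=species)
            records.append(rec)
            truth.proteins[rec.id] = t
        sp_loci, sp_truth = make_genome(config, rng, species=species)
        loci.extend(sp_loci)
        truth.loci.update(sp_truth.loci)
    d = 0
    for kind, count in config.decoy_counts.items():
        for _ in range(count):
            d += 1
            rec, t = make_decoy(kind, rng, record_id=f"decoy{d:03d}_{kind}",
                                species=config.species[0])
            records.append(rec)
            truth.proteins[rec.id] = t
    return Benchmark(config=config, records=records, loci=loci, truth=truth,
                     references=reference_freds())
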