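"""End-to-end orchestration: scan -> classify -> motifs/assembly -> FReD
phylogeny -> synteny -> combined verdict, with a machine-readable report.

The combined-evidence rule lets synteny override the FReD label when the
neighborhood evidence is strong (score >= 0.3): single-domain phylogeny
misplaces fast-evolving paralogs (TNW and TNX FReDs sit on long branches),
while gene neighborhoods persist through those rate shifts.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from . import config as _config
from . import domain_scan, motif_scan, phylo, synteny
from .records import (
    AnnotationMethod,
    DomainAnnotation,
    GeneLocus,
    ProteinRecord,
    TenascinCall,
)
from .seqio import _jsonable
from .synthetic_data import make_reference_tnc, reference_freds

log = logging.getLogger(__name__)

__version__ = "0.1.0"

#: synteny may override the FReD label only at or above this score
SYNTENY_OVERRIDE_FLOOR = 0.3


def combine_evidence(fred_label: Optional[str], fred_margin: Optional[float],
                     synteny_label: Optional[str], synteny_score: Optional[float]
                     ) -> tuple[str, bool]:
    """Merge the two independent classification routes into a final label.

    Agreement wins outright; on disagreement a confident neighborhood
    (score >= 0.3) overrides the FReD label with a CONFLICT flag; with no
    synteny evidence the FReD label stands; two UNCLASSIFIED routes give
    TN_UNCLASSIFIED.  Returns (final_label, conflict_flag).
    """
    f = fred_label if fred_label not in (None, "UNCLASSIFIED") else None
    s = synteny_label if synteny_label not in (None, "UNCLASSIFIED") else None
    if f and s:
        if f == s:
            return f, False
        if (synteny_score or 0.0) >= SYNTENY_OVERRIDE_FLOOR:
            return s, True
        return f, True
    if s and (synteny_score or 0.0) >= SYNTENY_OVERRIDE_FLOOR:
        return s, False
    if f:
        return f, False
    return "TN_UNCLASSIFIED", False


@dataclass
class PipelineInputs:
    proteins: list[ProteinRecord]
    external_domains: Optional[list[DomainAnnotation]] = None
    loci: Optional[list[GeneLocus]] = None
    references: Optional[list[tuple[str, str, str]]] = None
    fragment_ids: set = field(default_factory=set)
    egf_mode: str = "strict"
    seed: int = 0
    window_k: int = 5
    bootstrap_reps: int = 0


def _locus_matches_protein(symbol: str, protein_id: str) -> bool:
    s, p = symbol.upper(), protein_id.upper()
    return s == p or p.endswith("_" + s)


def _synteny_for_proteins(inputs: PipelineInputs, calls: dict[str, TenascinCall]
                          ) -> list[dict]:
    """Profile every locus matching a called tenascin, assign by markers,
    apply the TNW adjacency rule, then attach the best-supported assignment
    per protein (duplicated WGD copies vote; highest score wins)."""
    marker_sets = _config.marker_sets()
    synonyms = _config.symbol_synonyms()
    assignments: list[dict] = []
    by_species_chrom: dict[tuple, list[GeneLocus]] = {}
    for g in inputs.loci or []:
        by_species_chrom.setdefault((g.species, g.chrom), []).append(g)
    for (species, chrom), _pool in sorted(by_species_chrom.items()):
        seen: set[str] = set()
        for g in sorted(_pool, key=lambda x: x.start):
            if g.symbol in seen:
                continue
            seen.add(g.symbol)
            matched = [pid for pid in calls if _locus_matches_protein(g.symbol, pid)]
            if not matched:
                continue
            prof = synteny.neighbor_profile(inputs.loci, g.symbol, species,
                                            k=inputs.window_k, chrom=chrom)
            label, score, runner = synteny.synteny_assign(prof, marker_sets, synonyms)
            assignments.append({
                "species": species, "chrom": chrom, "symbol": g.symbol,
                "profile": prof, "label": label, "score": score,
                "runner_up": runner, "protein_ids": matched,
            })
    synteny.apply_tnw_adjacency(assignments, marker_sets, synonyms)
    # A protein product maps to exactly one genomic locus, but after a WGD
    # the symbol alone cannot say which copy; degraded duplicates can
    # perfectly imitate the sibling paralog's neighborhood (a surviving TNW
    # copy whose TNR partner was deleted sits adjacent to COP1).  The
    # protein's own FReD label is therefore the first tie-breaker between
    # candidate copies; neighborhood preservation (marker fraction, marker
    # count) and score order the rest.  A genuine single-locus disagreement
    # still reaches the synteny-over-FReD rule in combine_evidence.
    best_key: dict[str, tuple] = {}
    for a in assignments:
        ms = marker_sets.get(a["label"], {})
        a["n_markers"] = len(synteny.matched_markers(a["profile"], ms, synonyms))
        a["marker_fraction"] = a["n_markers"] / len(ms) if ms else 0.0
        for pid in a["protein_ids"]:
            call = calls[pid]
            if call.species and call.species != a["species"]:
                continue
            key = (a["label"] == call.fred_label,
                   a["marker_fraction"], a["n_markers"], a["score"])
            if pid not in best_key or key > best_key[pid]:
                best_key[pid] = key
                call.synteny_label = a["label"]
                call.synteny_score = round(a["score"], 4)
    return assignments


def run_pipeline(inputs: PipelineInputs) -> dict:
    """Execute the full analysis over in-memory inputs; deterministic given
    the inputs and seed.  Optional inputs degrade gracefully: without a locus
    table the synteny fields stay null; without equal-length FReDs no tree is
    built (external alignments can be fed to the phylo module directly)."""
    references = inputs.references or reference_freds()
    reference_record = make_reference_tnc()
    external_by_pid: dict[str, list[DomainAnnotation]] = {}
    for ann in inputs.external_domains or []:
        external_by_pid.setdefault(ann.protein_id, []).append(ann)

    calls: dict[str, TenascinCall] = {}
    freds: dict[str, str] = {}
    n_scanned = 0
    for rec in inputs.proteins:
        n_scanned += 1
        anns = list(external_by_pid.get(rec.id, []))
        anns += domain_scan.annotate_builtin(rec, egf_mode=inputs.egf_mode)
        arch = domain_scan.build_architecture(rec, anns)
        is_tn, reasons = domain_scan.classify_architecture(
            arch, fragment=rec.id in inputs.fragment_ids)
        call = TenascinCall(
            protein_id=rec.id, species=rec.species, is_tenascin=is_tn,
            reasons=reasons,
            architecture={"n_egf": arch.n_egf, "n_fn3": arch.n_fn3,
                          "has_signal": arch.has_signal,
                          "has_terminal_fred": arch.has_terminal_fred,
                          "length": arch.seq_length})
        if is_tn:
            call.motifs = [vars(h) for h in
                           motif_scan.find_integrin_motifs(arch, rec.seq)]
            try:
                profile = motif_scan.profile_assembly_region(
                    rec, arch, reference_record)
                call.assembly = _jsonable({
                    "region": profile.region,
                    "cysteines": {str(k): v for k, v in profile.cysteines.items()},
                    "heptad": vars(profile.heptad) if profile.heptad else None,
                    "rhexle_present": profile.rhexle_present,
                    "conserved_motifs": profile.conserved_motif_hits})
            except ValueError as exc:
                log.warning("%s: assembly profiling skipped (%s)", rec.id, exc)
            fred = phylo.extract_fred(arch, rec.seq)
            freds[rec.id] = fred
            label, margin = phylo.assign_paralog_by_fred(fred, references)
            call.fred_label = label
            call.fred_margin = round(margin, 2)
        calls[rec.id] = call

    synteny_table: list[dict] = []
    if inputs.loci:
        synteny_table = _synteny_for_proteins(inputs, calls)

    for call in calls.values():
        if not call.is_tenascin:
            call.final_label = "NOT_TENASCIN"
            continue
        call.final_label, call.conflict = combine_evidence(
            call.fred_label, call.fred_margin,
            call.synteny_label, call.synteny_score)

    tree_newick = None
    lengths = {len(s) for s in freds.values()}
    if len(freds) >= 3 and len(lengths) == 1:
        tree = phylo.neighbor_joining(phylo.p_distance_matrix(freds))
        if inputs.bootstrap_reps > 0:
            tree = phylo.bootstrap_support(freds, inputs.bootstrap_reps,
                                           seed=inputs.seed)
        tree_newick = tree.to_newick()

    inventory: dict[str, dict[str, int]] = {}
    for call in calls.values():
        if call.is_tenascin:
            sp = call.species or "unknown"
            inventory.setdefault(sp, {})
            inventory[sp][call.final_label] = \
                inventory[sp].get(call.final_label, 0) + 1

    cfg_repr = json.dumps({
        "egf_mode": inputs.egf_mode, "seed": inputs.seed,
        "window_k": inputs.window_k, "bootstrap_reps": inputs.bootstrap_reps,
        "fragments": sorted(inputs.fragment_ids)}, sort_keys=True)
    report = {
        "run": {
            "tool": "tenascope",
            "version": __version__,
            "seed": inputs.seed,
            "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
            "n_proteins": n_scanned,
            "n_tenascins": sum(c.is_tenascin for c in calls.values()),
            "egf_mode": inputs.egf_mode,
        },
        "calls": [calls[pid].to_dict() for pid in sorted(calls)],
        "inventory": inventory,
        "tree": tree_newick,
        "synteny": _jsonable([
            {k: v for k, v in a.items() if k != "profile"}
            for a in synteny_table]),
    }
    validate_report(report)
    return report


# ------------------------------------------------------------ report schema

def _load_schema() -> dict:
    with resources.files("tenascope.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def _check_type(value, expected, where: str):
    types = {"object": dict, "array": list, "string": str, "boolean": bool,
             "number": (int, float), "null": type(None)}
    allowed = expected if isinstance(expected, list) else [expected]
    if not any(isinstance(value, types[t]) for t in allowed):
        raise ValueError(f"report field {where}: expected {expected}, "
                         f"got {type(value).__name__}")


def validate_report(report: dict) -> None:
    """Validate the report against the packaged structural schema; raises
    ValueError on the first violation."""
    schema = _load_schema()
    for key, spec in schema["required"].items():
        if key not in report:
            raise ValueError(f"report missing field {key!r}")
        _check_type(report[key], spec["type"], key)
        for sub, t in spec.get("required", {}).items():
            if sub not in report[key]:
                raise ValueError(f"report missing field {key}.{sub}")
            _check_type(report[key][sub], t, f"{key}.{sub}")
        if "item_required" in spec:
            for i, item in enumerate(report[key]):
                for sub, t in spec["item_required"].items():
                    if sub not in item:
                        raise ValueError(f"report missing {key}[{i}].{sub}")
                    _check_type(item[sub], t, f"{key}[{i}].{sub}")
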