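"""End-to-end driver: ingest -> map -> extract -> templates -> report."""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional

from . import io as rio
from .extraction import (
    build_reactive_center,
    correct_peroxide_elimination,
    detect_changes,
    mechanism_acceptable,
)
from .mapping import (
    complete_symmetric_gap,
    compute_mapping,
    select_resonance_combination,
    validate_mapping,
)
from .templates import (
    ReactionTemplate,
    build_template,
    deduplicate_and_count,
    distribution_rows,
    generate_constraints,
    templates_to_yaml,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: str
    input_format: str  # list | rxn | chemkin | rxnd
    mapper: str = "baseline"  # baseline | premapped
    include_hetero: bool = True
    max_reactants: int = 2
    use_resonance: bool = True
    seed: int = 42
    out_dir: str = "out"


@dataclass
class RecordResult:
    source_id: str
    mapping_state: str = ""
    mechanism_ok: bool = True
    detail: str = ""
    template: Optional[ReactionTemplate] = None


def load_corpus(path: str, fmt: str) -> rio.Corpus:
    if fmt == "list":
        return rio.read_identifier_list(path)
    if fmt == "rxn":
        return rio.read_rxn_directory(path)
    if fmt == "chemkin":
        return rio.read_chemkin(path)
    if fmt == "rxnd":
        return rio.read_corpus(path)
    raise ValueError(f"unknown input format {fmt!r}")


def process_record(
    record: rio.ReactionRecord,
    mapper: str = "baseline",
    include_hetero: bool = True,
    use_resonance: bool = True,
    mapper_fn: Optional[Callable] = None,
) -> RecordResult:
    """Map (or adopt a pre-determined mapping), extract and formalize one record."""
    res = RecordResult(record.source_id)
    working = record
    if record.mapping is not None and validate_mapping(record, record.mapping).state == "complete":
        amap = record.mapping
        res.mapping_state = "complete"
    elif mapper == "premapped":
        res.mapping_state = "failed"
        res.detail = "premapped mapper selected but no complete mapping present"
        return res
    else:
        if use_resonance:
            working, amap = select_resonance_combination(record, mapper_fn)
        else:
            amap = compute_mapping(record, mapper_fn)
        status = validate_mapping(working, amap)
        if status.state == "incomplete":
            amap, status = complete_symmetric_gap(working, amap)
        res.mapping_state = status.state
        res.detail = status.detail
        if status.state not in ("complete", "heuristically_completed"):
            return res

    amap = correct_peroxide_elimination(working, amap)
    changes = detect_changes(working, amap)
    ok, reason = mechanism_acceptable(working, changes)
    if not ok:
        res.mechanism_ok = False
        res.detail = reason
        return res
    center = build_reactive_center(working, changes, include_hetero)
    res.template = build_template(working, amap, changes, center)
    return res


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, write artifacts to the output directory and return the
    run manifest (also written as ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    corpus = load_corpus(config.input_path, config.input_format)
    manifest["stages"]["parsed"] = len(corpus.records)

    balanced, rejects = rio.filter_unbalanced(corpus)
    manifest["stages"]["rejected_balance"] = len(rejects)
    manifest["balance_rejects"] = rejects

    sized = rio.filter_arity(balanced, config.max_reactants)
    manifest["stages"]["rejected_arity"] = len(balanced.records) - len(sized.records)
    manifest["stages"]["mapped_attempted"] = len(sized.records)

    mapping_counts = {
        "complete": 0,
        "heuristically_completed": 0,
        "incomplete": 0,
        "failed": 0,
    }
    mech_rejected = 0
    results: list[RecordResult] = []
    templates: list[ReactionTemplate] = []
    for rec in sized.records:
        res = process_record(
            rec,
            mapper=config.mapper,
            include_hetero=config.include_hetero,
            use_resonance=config.use_resonance,
        )
        results.append(res)
        mapping_counts[res.mapping_state] = mapping_counts.get(res.mapping_state, 0) + 1
        if not res.mechanism_ok:
            mech_rejected += 1
            continue
        if res.template is not None:
            templates.append(res.template)

    manifest["stages"]["mapping"] = mapping_counts
    manifest["stages"]["mechanism_rejected"] = mech_rejected
    manifest["stages"]["unmapped_or_rejected"] = (
        mapping_counts["incomplete"] + mapping_counts["failed"] + mech_rejected
    )

    table = deduplicate_and_count(templates)
    for tpl in table:
        tpl.constraints = generate_constraints(sized, tpl) if sized.records else []
    manifest["stages"]["templates"] = len(table)
    manifest["stages"]["templates_identical"] = sum(
        1 for t in table if t.status == "identical"
    )
    manifest["stages"]["reverse_linked"] = sum(
        1 for t in table if t.reverse_of is not None
    )
    class_dist: dict[str, int] = {}
    for t in table:
        top = t.class_path.split("/")[0]
        class_dist[top] = class_dist.get(top, 0) + t.count
    manifest["class_distribution"] = class_dist

    (out / "templates.yaml").write_text(templates_to_yaml(table))
    with (out / "distribution.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["id", "class", "count", "reverse_of", "status"]
        )
        writer.writeheader()
        writer.writerows(distribution_rows(table))
    key_to_id = {t.key(): t.template_id for t in table}
    with (out / "records.jsonl").open("w") as fh:
        for res in results:
            fh.write(
                json.dumps(
                    {
                        "source_id": res.source_id,
                        "mapping_state": res.mapping_state,
                        "mechanism_ok": res.mechanism_ok,
                        "detail": res.detail,
                        "template": key_to_id.get(res.template.key())
                        if res.template is not None
                        else None,
                    }
                )
                + "\n"
            )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    manifest["_table"] = table
    manifest["_results"] = results
    return manifest


def analyze_network(path: str | Path, include_hetero: bool = True, out_dir: Optional[str] = None) -> dict:
    """Full analysis of one CHEMKIN network; headline numbers only."""
    import tempfile

    config = RunConfig(
        str(path),
        "chemkin",
        include_hetero=include_hetero,
        out_dir=out_dir or tempfile.mkdtemp(prefix="rxntemplater_"),
    )
    manifest = run_pipeline(config)
    table = manifest["_table"]
    st = manifest["stages"]
    analyzed = sum(t.count for t in table)
    h_abs = sum(
        t.count for t in table if t.class_path.startswith("hydrogen_abstraction")
    )
    return {
        "parsed": st["parsed"],
        "templates": st["templates"],
        "reverse_linked": st["reverse_linked"],
        "unmapped_or_rejected": st["unmapped_or_rejected"],
        "analyzed": analyzed,
        "h_abstraction_share": 100.0 * h_abs / analyzed if analyzed else 0.0,
    }
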