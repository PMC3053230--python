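"""End-to-end orchestration: scan -> rank -> thread -> interface -> report,
and broods -> rescue report.

Both pipelines are deterministic functions of their config and inputs:
every output file carries the SHA-256 hash of the resolved config, and a
rerun on identical inputs produces byte-identical JSON (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .rescue import RescueModel, RescueThresholds, lines_from_dataframe
from .sequences import (
    ProteinSequence,
    SpacingModel,
    assign_unique,
    pairwise_global_align,
    scan_ring_ligands,
)
from .structures import (
    StructureModel,
    TemplateEntry,
    interface_residues,
    rank_templates,
    read_structure,
    thread_model,
    write_structure,
)

log = logging.getLogger("ringscape")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


_STRUCTURE_KEYS = {
    "query_fasta", "query_offset", "templates", "partner_chain",
    "cutoff", "gap_ranges", "mode", "weights", "out_dir",
}
_RESCUE_KEYS = {
    "broods_csv", "reference", "weighting", "thresholds",
    "compensation_triples", "bootstrap", "seed", "out_dir",
}


@dataclass
class PipelineConfig:
    """Validated configuration for either pipeline.

    Structure side: ``query_fasta``, ``query_offset``, ``templates`` (list
    of {id, pdb, chain, ligand_positions}), ``partner_chain``, ``cutoff``,
    optional ``gap_ranges``/``mode``/``weights``.  Rescue side:
    ``broods_csv``, ``reference``, ``weighting``, ``thresholds``,
    ``compensation_triples``, ``bootstrap``, ``seed``.  Unknown keys are
    rejected up front.
    """

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.raw) - _STRUCTURE_KEYS - _RESCUE_KEYS
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise PipelineError("config", f"config root must be a mapping: {path}")
        return cls(data)

    def get(self, key, default=None):
        return self.raw.get(key, default)

    def require(self, key, stage: str):
        if key not in self.raw:
            raise PipelineError(stage, f"missing required config key {key!r}")
        return self.raw[key]

    @property
    def hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, payload: dict, config_hash: str) -> None:
    payload = {"config_hash": config_hash, "ringscape_version": __version__, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _spacing_model(config: PipelineConfig) -> SpacingModel:
    gaps = config.get("gap_ranges")
    mode = config.get("mode", "c4c4")
    kwargs = {}
    if gaps is not None:
        kwargs["gap_ranges"] = tuple(tuple(g) for g in gaps)
    if mode == "c4c4":
        return SpacingModel.c4c4(**kwargs)
    if mode == "c3hc4":
        return SpacingModel.c3hc4(**kwargs)
    raise PipelineError("config", f"unknown spacing mode {mode!r}")


def run_structure_pipeline(config: PipelineConfig) -> dict:
    """Scan the query, rank templates, thread on the best, call interface.

    Writes scan.json, ranking.tsv, model.pdb, interface.tsv/.json and a
    combined report.json into ``out_dir``; returns the combined report.
    """
    out_dir = Path(config.require("out_dir", "setup"))
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.hash

    # --- stage: scan ------------------------------------------------------
    try:
        fasta = config.require("query_fasta", "scan")
        offset = int(config.get("query_offset", 1))
        query = ProteinSequence.from_fasta(fasta, offset)[0]
        model = _spacing_model(config)
        assignments = scan_ring_ligands(query, model)
        assignment = assign_unique(assignments)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("scan", str(e)) from e
    log.info("stage=scan query=%s assignments=1 positions=%s", query.id, assignment.positions)
    _write_json(out_dir / "scan.json", {"query": query.id, **assignment.to_dict()}, chash)

    # --- stage: rank-templates -------------------------------------------
    try:
        tmpl_cfgs = config.require("templates", "rank-templates")
        entries = []
        for t in tmpl_cfgs:
            st = read_structure(t["pdb"])
            entries.append(
                TemplateEntry(
                    template_id=t["id"],
                    structure=st,
                    chain_id=t.get("chain") or next(iter(st.chains)),
                    ligand_positions=tuple(t.get("ligand_positions", ())),
                )
            )
        weights = tuple(config.get("weights", (1.0, 1.0, 1.0)))
        scores = rank_templates(query, assignment, entries, weights)
        if not scores:
            raise PipelineError(
                "rank-templates", "no usable template (all lack ligand annotations)"
            )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("rank-templates", str(e)) from e
    ranking = pd.DataFrame([asdict(s) for s in scores])
    ranking.to_csv(out_dir / "ranking.tsv", sep="\t", index=False)
    best = next(e for e in entries if e.template_id == scores[0].template_id)
    log.info("stage=rank-templates best=%s n=%d", best.template_id, len(scores))

    # --- stage: thread ----------------------------------------------------
    try:
        aln = pairwise_global_align(query, best.sequence)
        threaded = thread_model(query, best.structure, aln, best.chain_id)
    except Exception as e:
        raise PipelineError("thread", str(e)) from e
    write_structure(threaded, out_dir / "model.pdb")
    log.info("stage=thread template=%s unmodeled=%d", best.template_id, len(threaded.unmodeled))

    # --- stage: interface -------------------------------------------------
    try:
        cutoff = float(config.get("cutoff", 5.0))
        partner_chain = config.require("partner_chain", "interface")
        if partner_chain not in best.structure.chains:
            raise PipelineError(
                "interface",
                f"partner chain {partner_chain!r} absent from template "
                f"{best.template_id}",
            )
        partner = StructureModel(
            {partner_chain: best.structure.chains[partner_chain]}
        )
        report = interface_residues(threaded, partner, cutoff)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("interface", str(e)) from e
    iface = pd.DataFrame(report.to_records())
    iface.to_csv(out_dir / "interface.tsv", sep="\t", index=False)
    _write_json(
        out_dir / "interface.json",
        {"cutoff": cutoff, "residues": report.to_records()},
        chash,
    )
    log.info("stage=interface cutoff=%.1f residues=%d", cutoff, len(report.residues))

    combined = {
        "query": query.id,
        "assignment": assignment.to_dict(),
        "template_ranking": ranking.to_dict(orient="records"),
        "best_template": best.template_id,
        "alignment_identity": aln.report.percent_identity,
        "unmodeled_residues": [list(u) for u in threaded.unmodeled],
        "interface": {"cutoff": cutoff, "residues": report.to_records()},
    }
    _write_json(out_dir / "report.json", combined, chash)
    return combined


def run_rescue_pipeline(config: PipelineConfig) -> dict:
    """Per-line summaries, rescue fractions, classifications, compensation
    verdicts and bootstrap intervals from a brood CSV."""
    out_dir = Path(config.require("out_dir", "setup"))
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.hash
    try:
        csv = config.require("broods_csv", "rescue")
        df = pd.read_csv(csv, dtype={"mean": str})
        if df.empty:
            raise PipelineError("rescue", f"no rows in {csv}")
        thresholds = config.get("thresholds")
        model = RescueModel.from_dataframe(
            df,
            reference=config.get("reference", "wild type"),
            weighting=config.get("weighting", "unweighted"),
            thresholds=RescueThresholds(**thresholds) if thresholds else None,
        )
        results = model.fit(
            bootstrap=int(config.get("bootstrap", 0)),
            seed=int(config.get("seed", 0)),
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("rescue", str(e)) from e
    frame = results.to_frame()
    frame.to_csv(out_dir / "rescue.tsv", sep="\t", index=False)
    verdicts = {}
    for triple in config.get("compensation_triples", []):
        a, b, d = triple
        res = results.compensation(a, b, d)
        verdicts[f"{a} / {b} / {d}"] = {
            "single_a": res.single_a,
            "single_b": res.single_b,
            "double": res.double,
            "verdict": res.verdict,
        }
    log.info("stage=rescue genotypes=%d verdicts=%d", len(frame), len(verdicts))
    payload = {
        "reference": model.reference,
        "weighting": model.weighting,
        "genotypes": frame.to_dict(orient="records"),
        "compensation": verdicts,
        "exclusions": model.exclusion_log,
    }
    _write_json(out_dir / "rescue.json", payload, chash)
    return payload
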