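"""End-to-end pipeline: shifts -> NOE classification -> turn inference ->
restraints -> fragment refinement -> structural turn consensus.

Every stage writes its artifact under the configured output directory and
registers itself in a MANIFEST; the machine-readable summary.json carries
the NOE-inferred turn hypotheses, the per-fragment ensembles' consensus
calls and restraint-violation statistics.  A fixed seed reproduces the whole
run bit for bit.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .builder import CapSpec, build_extended, write_pdb
from .noe import (NoeSet, classify_peak, infer_turns, proline_isomer,
                  restraints_from_noes, turn_hbond_restraints, write_xplor)
from .refine import RefinementConfig, refine_ensemble, violation_report
from .sequences import PROLINE_CODES, Sequence, parse_sequence
from .shifts import csi_segments, parse_shift_table, secondary_shifts, write_long_tsv
from .turns import ensemble_turn_consensus

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 2

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sequence: str
    sequence_start: int = 1
    shift_table: str | None = None
    noe_table: str | None = None
    peptide_id: str = "peptide"
    calibration: str = "uniform"
    consensus_fraction: float = 0.6
    fragment_flank: int = 2  # residues either side of each 4-residue turn
    add_turn_hbonds: bool = True
    refinement: dict = field(default_factory=dict)
    out_dir: str = "noeturn_out"
    seed: int = 0

    @property
    def parsed_sequence(self) -> Sequence:
        return parse_sequence(self.sequence, start=self.sequence_start,
                              label=self.peptide_id)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _refinement_config(cfg: PipelineConfig, seed: int) -> RefinementConfig:
    kwargs = dict(cfg.refinement)
    kwargs["seed"] = seed
    if "temperature_schedule" in kwargs:
        kwargs["temperature_schedule"] = tuple(
            (int(s), float(t)) for s, t in kwargs["temperature_schedule"]
        )
    return RefinementConfig(**kwargs)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the JSON-serialisable summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "noeturn_version": __version__,
        "peptide_id": cfg.peptide_id,
        "seed": cfg.seed,
    }
    sequence = cfg.parsed_sequence

    for name in ("shift_table", "noe_table"):
        path = getattr(cfg, name)
        if path is not None and not Path(path).exists():
            raise PipelineError("config", f"{name} file not found: {path}")

    # ---- stage: shifts ---------------------------------------------------
    if cfg.shift_table is not None:
        try:
            table = parse_shift_table(Path(cfg.shift_table).read_text(),
                                      sequence, cfg.peptide_id)
            deltas = secondary_shifts(table)
            ha = [(i, d) for i, n, d in deltas if n == "HA"]
            segments = csi_segments(ha)
            (out / "shifts_long.tsv").write_text(write_long_tsv(table))
            summary["shifts"] = {
                "n_records": len(table.records),
                "residues_assigned": table.residues,
                "csi_segments": [
                    {"start": s, "end": e, "label": l} for s, e, l in segments
                ],
            }
            manifest.append("shifts")
        except PipelineError:
            raise
        except Exception as exc:
            _fail(out, manifest, "shifts", exc)

    # ---- stage: NOE classification and turn inference --------------------
    if cfg.noe_table is None:
        raise PipelineError("config", "a NOE table is required")
    try:
        noes = NoeSet.from_tsv(Path(cfg.noe_table).read_text())
        classified = [(p, classify_peak(p, sequence)) for p in noes]
        hypotheses = infer_turns(noes, sequence)
        isomers = {
            i: proline_isomer(noes, i, sequence)
            for i in sequence.indices if sequence.code(i) in PROLINE_CODES
        }
        summary["noe"] = {
            "n_peaks": len(noes),
            "classes": {
                f"{p.residue_i}{p.atom_i}-{p.residue_j}{p.atom_j}": c
                for p, c in classified
            },
            "proline_isomers": isomers,
            "turns": [
                {"start": h.start, "end": h.end, "type": h.turn_type,
                 "ambiguous": h.ambiguous, "n_evidence": len(h.evidence)}
                for h in hypotheses
            ],
        }
        manifest.append("noe")
    except Exception as exc:
        _fail(out, manifest, "noe", exc)

    # ---- stage: restraints ----------------------------------------------
    try:
        restraints = restraints_from_noes(noes, sequence, cfg.calibration)
        (out / "restraints.tsv").write_text(restraints.to_tsv())
        (out / "restraints.xplor").write_text(write_xplor(restraints))
        summary["restraints"] = {"n": len(restraints),
                                 "calibration": cfg.calibration}
        manifest.append("restraints")
    except Exception as exc:
        _fail(out, manifest, "restraints", exc)

    # ---- per-turn fragments: build + refine + consensus ------------------
    fragments = []
    for fi, hyp in enumerate(hypotheses):
        frag_start = max(sequence.start, hyp.start - cfg.fragment_flank)
        frag_end = min(sequence.end, hyp.end + cfg.fragment_flank)
        frag_seq = sequence.subsequence(frag_start, frag_end)
        try:
            conf = build_extended(frag_seq, CapSpec())
            frag_restraints = _restraints_in_window(restraints, frag_start, frag_end)
            if cfg.add_turn_hbonds:
                frag_restraints = frag_restraints + turn_hbond_restraints(hyp)
            rcfg = _refinement_config(cfg, seed=cfg.seed + fi)
            ens = refine_ensemble(conf, frag_restraints, rcfg)
            pdb_path = out / f"fragment_{frag_start}-{frag_end}.pdb"
            write_pdb(pdb_path, ens.snapshots)
            report = violation_report(ens)
            (out / f"fragment_{frag_start}-{frag_end}_violations.tsv").write_text(
                _violations_tsv(report, frag_restraints)
            )
            consensus = ensemble_turn_consensus(ens, cfg.consensus_fraction)
            fragments.append({
                "turn_hypothesis": {"start": hyp.start, "end": hyp.end,
                                    "type": hyp.turn_type},
                "fragment": [frag_start, frag_end],
                "n_snapshots": len(ens),
                "n_restraints": len(frag_restraints),
                "violation_satisfied_fraction": report.satisfied_fraction,
                "ensemble_pdb": pdb_path.name,
                "consensus": [
                    {"start": c.start, "end": c.end, "type": c.turn_type,
                     "fraction": frac,
                     "mean_ca_distance_nm": round(c.ca_distance, 4)}
                    for c, frac in consensus
                ],
            })
        except Exception as exc:
            _fail(out, manifest, f"refine[{frag_start}-{frag_end}]", exc)
    summary["fragments"] = fragments
    manifest.append("refine")
    manifest.append("consensus")

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
    return summary


def _restraints_in_window(restraints, start, end):
    from .noe import RestraintSet

    return RestraintSet([
        r for r in restraints
        if start <= r.residue_i <= end and start <= r.residue_j <= end
    ])


def _violations_tsv(report, restraints) -> str:
    rows = ["snapshot\tres_i\tatom_i\tres_j\tatom_j\tupper_nm\tdistance_nm"
            "\texcess_nm\tenergy_kj_mol"]
    recs = list(restraints)
    for s in range(report.instantaneous.shape[0]):
        for k, r in enumerate(recs):
            rows.append(
                f"{s}\t{r.residue_i}\t{r.atom_i}\t{r.residue_j}\t{r.atom_j}"
                f"\t{r.upper_bound:g}\t{report.instantaneous[s, k]:.4f}"
                f"\t{report.excess[s, k]:.4f}\t{report.energy[s, k]:.4f}"
            )
    return "\n".join(rows) + "\n"


def _fail(out, manifest, stage, exc):
    (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
    raise PipelineError(stage, str(exc)) from exc
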