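"""End-to-end orchestration: structures + sequences + variants in,
renumbered structures, mutant models, SASA comparisons and a summary
table out.

For every structure chain the observed sequence is aligned against every
canonical sequence in the FASTA and the best-scoring accession is taken
as the chain's protein (deterministic; ties resolved by FASTA order).
Each matching (variant, structure, chain) combination yields one output
row; a model file is built only when the chain passed quality control and
the variant placed cleanly.  Per-record failures are logged and recorded
as rows, never fatal.

Everything is deterministic for a fixed configuration: re-running
produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import AlignParams
from .mutate import mutate_residue
from .pdbio import chain_sequence, parse_structure, write_structure
from .renumber import (QCError, apply_renumbering, build_mapping,
                       mapping_to_tsv, qc_evaluate, read_canonical_fasta)
from .sasa import SASAParams, compare_sasa, compute_sasa
from .variants import parse_variants, place_variant

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "OUTPUT_COLUMNS", "load_config_file"]

log = logging.getLogger("protvarmap")

ANNOTATION_COLUMNS = ("polyphen2", "sift", "drugbank", "active_site",
                      "metal_site")
OUTPUT_COLUMNS = (
    "gene", "rs_id", "accession", "pdb_id", "chain", "method",
    "resolution", "wt_aa3", "position", "mut_aa3", "status",
    "total_sasa_wt", "total_sasa_mut", "model_path",
) + ANNOTATION_COLUMNS


@dataclass
class PipelineConfig:
    structure_dir: str | Path
    fasta_path: str | Path
    variant_path: str | Path
    out_dir: str | Path
    align_params: AlignParams = field(default_factory=AlignParams)
    sasa_params: SASAParams = field(default_factory=SASAParams)
    chi_policy: dict[int, float] | None = None
    qc_override: bool = False       # renumber and model even if QC fails
    first_chain_only: bool = False  # one model per (variant, PDB entry)
    log_level: str = "INFO"

    def validate(self) -> None:
        for p in (self.structure_dir, self.fasta_path, self.variant_path):
            if not Path(p).exists():
                raise FileNotFoundError(str(p))


@dataclass
class PipelineResult:
    table: pd.DataFrame
    model_files: list[Path]
    counts: dict[str, int]


def load_config_file(path: str | Path) -> dict[str, str]:
    """Read a simple key=value configuration file."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _best_accession(obs, canons, p: AlignParams):
    """Best-scoring canonical sequence for an observed chain."""
    from .align import global_align

    best = None
    for acc, canon in canons.items():
        score = global_align(obs.letters, canon.sequence, p).score
        if best is None or score > best[1]:
            best = (acc, score)
    return best[0] if best else None


def run_pipeline(c: PipelineConfig) -> PipelineResult:
    c.validate()
    out_dir = Path(c.out_dir)
    (out_dir / "models").mkdir(parents=True, exist_ok=True)
    (out_dir / "renumbered").mkdir(exist_ok=True)
    (out_dir / "mappings").mkdir(exist_ok=True)
    logging.basicConfig(level=c.log_level)

    canons = read_canonical_fasta(c.fasta_path)
    raw = pd.read_csv(c.variant_path, sep="\t", dtype=str,
                      keep_default_na=False)
    report = parse_variants(Path(c.variant_path).read_text())
    counts: dict[str, int] = {
        "variant_rows_in": report.rows_in,
        "variants_retained": len(report.variants),
    }
    for reason, n in sorted(report.dropped_by_reason.items()):
        counts[f"dropped_{reason}"] = n
        log.info("dropped %d variant row(s): %s", n, reason)
    (out_dir / "drop_report.tsv").write_text(report.drop_report_tsv())

    # annotation pass-through, keyed by (rs digits, accession)
    annotations: dict[tuple[str, str], dict[str, str]] = {}
    for _, row in raw.iterrows():
        rs = str(row.get("rs_id", "")).strip()
        rs = rs[2:] if rs.lower().startswith("rs") else rs
        key = (rs, str(row.get("accession", "")).strip())
        annotations[key] = {
            col: str(row[col]) if col in raw.columns else ""
            for col in ANNOTATION_COLUMNS
        }

    rows: list[dict] = []
    model_files: list[Path] = []
    structure_paths = sorted(Path(c.structure_dir).glob("*.pdb")) + \
        sorted(Path(c.structure_dir).glob("*.ent"))

    for spath in structure_paths:
        try:
            s = parse_structure(spath.read_text())
        except Exception as e:  # noqa: BLE001 - per-record, never fatal
            log.error("unreadable structure %s: %s", spath.name, e)
            counts["structures_unreadable"] = \
                counts.get("structures_unreadable", 0) + 1
            continue
        chain_ids = list(s.chains)
        if c.first_chain_only:
            chain_ids = chain_ids[:1]
        for chain in chain_ids:
            obs = chain_sequence(s, chain)
            if not obs.letters:
                continue
            acc = _best_accession(obs, canons, c.align_params)
            if acc is None:
                continue
            canon = canons[acc]
            mapping = build_mapping(obs, canon, c.align_params)
            verdict = qc_evaluate(mapping)
            (out_dir / "mappings" / f"{s.pdb_id}_{chain}.tsv").write_text(
                mapping_to_tsv(mapping))
            renumbered = None
            if verdict.accepted or c.qc_override:
                renumbered, _ = apply_renumbering(s, mapping,
                                                  force=c.qc_override)
                (out_dir / "renumbered" /
                 f"{s.pdb_id}_{chain}.pdb").write_text(
                    write_structure(renumbered))
            wt_sasa = compute_sasa(s, c.sasa_params)

            for v in report.variants:
                if v.accession != acc:
                    continue
                row = {
                    "gene": v.gene, "rs_id": v.rs_id, "accession": acc,
                    "pdb_id": s.pdb_id, "chain": chain,
                    "method": s.method,
                    "resolution": ("" if s.resolution is None
                                   else f"{s.resolution:.2f}"),
                    "wt_aa3": v.ref_aa3, "position": v.position,
                    "mut_aa3": v.alt_aa3,
                    "total_sasa_wt": f"{wt_sasa.total:.1f}",
                    "total_sasa_mut": "", "model_path": "",
                }
                row.update(annotations.get((v.rs_id, acc), {
                    col: "" for col in ANNOTATION_COLUMNS}))
                if not verdict.accepted and not c.qc_override:
                    row["status"] = ";".join(sorted(verdict.reasons))
                    rows.append(row)
                    continue
                placed = place_variant(v, mapping, canon, s.pdb_id)
                row["status"] = placed.status
                if placed.status == "PLACED":
                    try:
                        model = mutate_residue(
                            renumbered, chain, v.position, v.alt_aa,
                            c.chi_policy, variant=v)
                    except (QCError, KeyError, ValueError) as e:
                        log.error("model build failed for %s: %s",
                                  v.rs_id, e)
                        row["status"] = "BUILD_FAILED"
                        rows.append(row)
                        continue
                    mpath = out_dir / "models" / model.filename
                    mpath.write_text(write_structure(model.structure))
                    model_files.append(mpath)
                    mut_sasa = compute_sasa(model.structure, c.sasa_params)
                    delta = compare_sasa(
                        compute_sasa(renumbered, c.sasa_params), mut_sasa)
                    row["total_sasa_mut"] = f"{mut_sasa.total:.1f}"
                    row["model_path"] = str(
                        mpath.relative_to(out_dir))
                    log.info("built %s (total SASA delta %+.1f)",
                             model.filename, delta.total)
                rows.append(row)

    table = pd.DataFrame(rows, columns=list(OUTPUT_COLUMNS))
    table.to_csv(out_dir / "output_table.tsv", sep="\t", index=False)
    counts["rows"] = len(table)
    counts["models"] = len(model_files)
    with (out_dir / "run.log").open("w") as fh:
        for k in sorted(counts):
            fh.write(f"{k}\t{counts[k]}\n")
    return PipelineResult(table, model_files, counts)
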