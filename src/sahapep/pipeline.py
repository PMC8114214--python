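"""End-to-end orchestration: synth -> repertoire -> motif -> allotype -> pocket.

A single YAML configuration drives all stages; every output is delimited
text under the chosen output directory, and a JSON manifest records the
configuration hash, seed, per-stage outputs and record counts so that
two runs with the same configuration can be compared stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    ConfigurationError,
    load_config,
    read_allele_fasta,
    read_group_map,
    read_peptide_table,
    read_similarity_matrix,
    write_allele_fasta,
    write_group_map,
    write_peptide_table,
    write_similarity_matrix,
)
from .allotype import assign_peptides_to_alleles, quantify_allotypes
from .motif import build_pfm, classify_consensus, small_bulky_usage
from .pocket import PocketModel, scan_database
from .repertoire import (
    length_distribution,
    replicate_reproducibility,
    summarize_repertoire,
    venn_overlap,
)
from .synth import (
    SyntheticConfig,
    default_config,
    generate_allele_set,
    generate_alpha_chain_digest,
    generate_peptidome,
    generate_similarity_matrix,
)

logger = logging.getLogger("sahapep")

STAGES = ("synth", "repertoire", "motif", "allotype", "pocket")


@dataclass
class RunManifest:
    """Record of one pipeline run: outputs and counts per stage."""

    config_hash: str
    seed: int
    version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def add_stage(self, name: str, outputs: list[Path], n_in: int, n_out: int) -> None:
        for p in outputs:
            if not Path(p).exists() or Path(p).stat().st_size == 0:
                raise RuntimeError(f"stage {name}: declared output {p} missing or empty")
        self.stages[name] = {
            "outputs": [str(p) for p in outputs],
            "n_in": n_in,
            "n_out": n_out,
        }

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _stringify_keys(obj):
    if isinstance(obj, Mapping):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(_stringify_keys(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def setup_logging(logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def run_pipeline(
    config: str | Path | Mapping | None,
    outdir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Run all stages from one configuration and write a manifest.

    ``config`` may be a YAML path, an already-parsed mapping, or None for
    the bundled study-like default. ``seed`` overrides the configured
    seed. Stages run in dependency order; any stage failure aborts with
    the stage named in the raised error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(outdir / "run.log")

    if config is None:
        cfg_dict: dict = {"synthetic": default_config().to_dict()}
    elif isinstance(config, (str, Path)):
        cfg_dict = load_config(config)
    else:
        cfg_dict = dict(config)
    syn_cfg = (
        SyntheticConfig.from_dict(cfg_dict["synthetic"])
        if "synthetic" in cfg_dict
        else default_config()
    )
    if seed is not None:
        syn_cfg.seed = int(seed)
    manifest = RunManifest(config_hash=cfg_dict and config_hash(cfg_dict) or "", seed=syn_cfg.seed)

    for name in STAGES:
        try:
            _run_stage(name, syn_cfg, cfg_dict, outdir, manifest)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest.write(outdir / "manifest.json")
    logger.info("pipeline complete; manifest at %s", outdir / "manifest.json")
    return manifest


def _run_stage(
    name: str,
    syn_cfg: SyntheticConfig,
    cfg_dict: Mapping,
    outdir: Path,
    manifest: RunManifest,
) -> None:
    inputs = cfg_dict.get("inputs", {})
    if name == "synth":
        rng = np.random.default_rng(syn_cfg.seed)
        pep = generate_peptidome(syn_cfg, rng)
        alleles = generate_allele_set(syn_cfg.allele_universe, rng=rng)
        digest = generate_alpha_chain_digest(alleles.all_alleles, syn_cfg.digest, rng=rng)
        matrix = generate_similarity_matrix(rng)
        peptide_path = outdir / "peptides.tsv"
        digest_path = outdir / "alpha_chain_digest.tsv"
        fasta_path = outdir / "alleles.fasta"
        group_path = outdir / "group_map.tsv"
        matrix_path = outdir / "similarity_matrix.tsv"
        truth_path = outdir / "ground_truth.json"
        write_peptide_table(pep.records, peptide_path)
        write_peptide_table(digest.records, digest_path)
        write_allele_fasta(alleles.all_alleles, fasta_path)
        write_group_map(alleles.group_map, group_path)
        write_similarity_matrix(matrix, matrix_path)
        truth_path.write_text(
            json.dumps(
                {
                    "planted_top": alleles.planted_top,
                    "query": alleles.query.name,
                    "reference": alleles.reference.name,
                    "digest_fractions": digest.planted_fractions,
                    "digest_present_replicates": digest.present_replicates,
                    "n_shared": len(pep.shared_sequences),
                    "unique_per_line": {
                        k: len(v) for k, v in pep.unique_by_line.items()
                    },
                },
                indent=2,
            )
        )
        manifest.add_stage(
            name,
            [peptide_path, digest_path, fasta_path, group_path, matrix_path, truth_path],
            n_in=len(syn_cfg.cell_lines),
            n_out=len(pep.records) + len(digest.records),
        )
        return

    # analysis stages read what synth (or the user's config) declared
    peptide_path = Path(inputs.get("peptides", outdir / "peptides.tsv"))
    if not peptide_path.exists():
        raise ConfigurationError(f"missing input file {peptide_path}")
    records = read_peptide_table(peptide_path)

    if name == "repertoire":
        summaries = summarize_repertoire(records)
        summary_path = outdir / "repertoire_summary.tsv"
        pd.DataFrame(
            [
                {
                    "cell_line": s.cell_line,
                    "n_total_observations": s.n_total_observations,
                    "n_unique_sequences": s.n_unique_sequences,
                    "n_unique_7_15": s.n_unique_7_15,
                    "pct_7_15": s.pct_display,
                }
                for s in summaries.values()
            ]
        ).to_csv(summary_path, sep="\t", index=False)
        lengths_path = outdir / "length_distribution.tsv"
        length_distribution(records, per_replicate=True).to_csv(
            lengths_path, sep="\t", index=False
        )
        repro_path = outdir / "replicate_reproducibility.tsv"
        repro = replicate_reproducibility(records)
        pd.DataFrame(
            [
                {"cell_line": line, "n_replicates": k, "percent": v}
                for line, dist in repro.items()
                for k, v in dist.items()
            ]
        ).to_csv(repro_path, sep="\t", index=False)
        overlap_path = outdir / "overlap.tsv"
        overlap = venn_overlap(records)
        pd.DataFrame(
            [
                {"region": "&".join(sorted(region)), "count": count}
                for region, count in sorted(
                    overlap.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                )
            ]
        ).to_csv(overlap_path, sep="\t", index=False)
        manifest.add_stage(
            name,
            [summary_path, lengths_path, repro_path, overlap_path],
            n_in=len(records),
            n_out=sum(s.n_unique_7_15 for s in summaries.values()),
        )
        return

    if name == "motif":
        outputs = []
        n_out = 0
        cell_lines = sorted({r.cell_line for r in records})
        consensus_rows = []
        for line in cell_lines:
            for L in (8, 9):
                try:
                    pfm = build_pfm(records, L, line)
                except ValueError:
                    continue
                path = outdir / f"pfm_{line}_{L}mer.tsv"
                pfm.freqs.to_csv(path, sep="\t")
                outputs.append(path)
                motif = classify_consensus(pfm)
                frame = motif.to_frame()
                frame.insert(0, "cell_line", line)
                frame.insert(1, "length", L)
                consensus_rows.append(frame)
                n_out += pfm.n_peptides
        consensus_path = outdir / "consensus_motifs.tsv"
        pd.concat(consensus_rows, ignore_index=True).to_csv(
            consensus_path, sep="\t", index=False
        )
        usage_path = outdir / "small_bulky_usage.tsv"
        small_bulky_usage(records).to_csv(usage_path, sep="\t", index=False)
        manifest.add_stage(
            name, [*outputs, consensus_path, usage_path], n_in=len(records), n_out=n_out
        )
        return

    if name == "allotype":
        digest_path = Path(inputs.get("alpha_chain_digest", outdir / "alpha_chain_digest.tsv"))
        fasta_path = Path(inputs.get("alleles", outdir / "alleles.fasta"))
        for p in (digest_path, fasta_path):
            if not p.exists():
                raise ConfigurationError(f"missing input file {p}")
        group_path = Path(inputs.get("group_map", outdir / "group_map.tsv"))
        group_map = read_group_map(group_path) if group_path.exists() else None
        alleles = read_allele_fasta(fasta_path, group_map)
        digest_records = read_peptide_table(digest_path)
        quants = quantify_allotypes(digest_records, alleles)
        quant_path = outdir / "allotype_quantification.tsv"
        pd.DataFrame(
            [
                {
                    "cell_line": line,
                    "group": g,
                    "n_replicates_detected": q.n_replicates_detected,
                    "retained": q.retained,
                    "mean_normalized_intensity": q.mean,
                    "sem_normalized_intensity": q.sem,
                    **{f"rep{r}": v for r, v in sorted(q.per_replicate.items())},
                }
                for line, by_group in quants.items()
                for g, q in sorted(by_group.items())
            ]
        ).to_csv(quant_path, sep="\t", index=False)
        manifest.add_stage(
            name,
            [quant_path],
            n_in=len(digest_records),
            n_out=sum(len(v) for v in quants.values()),
        )
        return

    if name == "pocket":
        fasta_path = Path(inputs.get("alleles", outdir / "alleles.fasta"))
        matrix_path = Path(inputs.get("similarity_matrix", outdir / "similarity_matrix.tsv"))
        for p in (fasta_path, matrix_path):
            if not p.exists():
                raise ConfigurationError(f"missing input file {p}")
        alleles = read_allele_fasta(fasta_path)
        matrix = read_similarity_matrix(matrix_path)
        by_name = {a.name: a for a in alleles}
        truth_path = outdir / "ground_truth.json"
        if truth_path.exists():
            truth = json.loads(truth_path.read_text())
            reference = by_name[truth["reference"]]
            query = by_name[truth["query"]]
        else:
            reference, query = alleles[0], alleles[1]
        db = [a for a in alleles if a.name not in (reference.name, query.name)]
        rows = []
        outputs = []
        for model in (PocketModel.b_pocket(matrix), PocketModel.f_pocket(matrix)):
            report = scan_database(query, db, model, reference)
            for rank, m in enumerate(report.matches, 1):
                rows.append(
                    {
                        "query": m.query,
                        "pocket": m.pocket,
                        "rank": rank,
                        "subject": m.subject,
                        "relative_score": m.relative_score,
                    }
                )
            if report.no_prediction:
                rows.append(
                    {
                        "query": query.name,
                        "pocket": model.name,
                        "rank": 0,
                        "subject": "no_prediction",
                        "relative_score": float("nan"),
                    }
                )
        matches_path = outdir / "pocket_matches.tsv"
        pd.DataFrame(rows).to_csv(matches_path, sep="\t", index=False)
        manifest.add_stage(name, [matches_path], n_in=len(db), n_out=len(rows))
        return

    raise ValueError(f"unknown stage {name!r}")
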