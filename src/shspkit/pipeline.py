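"""End-to-end pipeline: annotate → scan → motifs → classify → align →
region extraction → distances → BioNJ → monophyly report.

Every stage writes a re-loadable plain-text artifact (TSV / FASTA / newick /
PHYLIP), and a JSON manifest records the configuration, seed and package
version, so any stage can be re-run from saved intermediates.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .architecture import Reference, RegionAnnotation, delimit_regions, load_reference
from .classify import ClassificationResult, classify_sequence, summarize
from .motifs import MotifHit, find_all_motifs
from .msa import Alignment, extract_region_columns, progressive_align
from .pattern import CYANOPHAGE_SIGNATURE, PatternHit, scan_pattern
from .phylo import bionj, is_monophyletic, poisson_distance
from .seqio import SequenceRecord, read_fasta


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    input_fasta: str
    out_dir: str
    reference_alignment: str | None = None
    reference_feature_map: str | None = None
    extract_regions: bool = True
    p_cap: float = 0.95
    d_max: float = 10.0
    clade_file: str | None = None      # one taxon label per line
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def annotations_table(annotations: dict[str, RegionAnnotation]) -> pd.DataFrame:
    rows = []
    for ann in annotations.values():
        rows.append(
            {
                "sequence_id": ann.sequence_id,
                "length": ann.length,
                "n_arm_start": ann.n_arm[0] if ann.n_arm else -1,
                "n_arm_end": ann.n_arm[1] if ann.n_arm else -1,
                "acd_start": ann.acd_start,
                "acd_end": ann.acd_end,
                "c_ext_start": ann.c_ext[0] if ann.c_ext else -1,
                "c_ext_end": ann.c_ext[1] if ann.c_ext else -1,
                "l57_start": ann.l57_interval[0],
                "l57_end": ann.l57_interval[1],
                "beta7_column": ann.beta7_column,
                "acd_score": round(ann.acd_score, 4),
                **{
                    f"{feat}_interval": f"{lo}-{hi}"
                    for feat, (lo, hi) in sorted(ann.strand_map.items())
                },
            }
        )
    return pd.DataFrame(rows)


def motifs_table(hits: dict[str, list[MotifHit]]) -> pd.DataFrame:
    rows = []
    for sid, seq_hits in hits.items():
        for h in seq_hits:
            rows.append(
                {
                    "sequence_id": sid,
                    "kind": h.kind,
                    "positions": ",".join(map(str, h.positions)),
                    "residues": h.residues,
                    "region": h.region,
                    "flags": ";".join(f"{k}={v}" for k, v in sorted(h.context_flags.items())),
                }
            )
    return pd.DataFrame(rows, columns=["sequence_id", "kind", "positions", "residues", "region", "flags"])


def patterns_table(hits: dict[str, list[PatternHit]]) -> pd.DataFrame:
    rows = [
        {"sequence_id": sid, "start": h.start, "end": h.end, "matched": h.matched}
        for sid, seq_hits in hits.items()
        for h in seq_hits
    ]
    return pd.DataFrame(rows, columns=["sequence_id", "start", "end", "matched"])


def classification_table(results: list[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "label": r.label,
                "rule_fired": r.rule_fired,
                "n_evidence": len(r.evidence),
            }
            for r in results
        ]
    )


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage; write the output bundle; return in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    records: list[SequenceRecord] = stage("seqio", lambda: read_fasta(config.input_fasta))
    reference: Reference = stage(
        "reference",
        lambda: load_reference(config.reference_alignment, config.reference_feature_map),
    )
    annotations: dict[str, RegionAnnotation] = stage(
        "annotate", lambda: {r.id: delimit_regions(r, reference) for r in records}
    )
    pattern_hits: dict[str, list[PatternHit]] = stage(
        "scan", lambda: {r.id: scan_pattern(CYANOPHAGE_SIGNATURE, r) for r in records}
    )
    motif_hits: dict[str, list[MotifHit]] = stage(
        "motifs", lambda: {r.id: find_all_motifs(r, annotations[r.id]) for r in records}
    )
    results: list[ClassificationResult] = stage(
        "classify",
        lambda: [
            classify_sequence(annotations[r.id], pattern_hits[r.id], motif_hits[r.id])
            for r in records
        ],
    )
    annotations_table(annotations).to_csv(out / "regions.tsv", sep="\t", index=False)
    motifs_table(motif_hits).to_csv(out / "motifs.tsv", sep="\t", index=False)
    patterns_table(pattern_hits).to_csv(out / "signature_hits.tsv", sep="\t", index=False)
    classification_table(results).to_csv(out / "classification.tsv", sep="\t", index=False)
    summarize(results).to_csv(out / "summary.tsv", sep="\t", index=False)

    bundle: dict[str, object] = {
        "records": records,
        "annotations": annotations,
        "pattern_hits": pattern_hits,
        "motif_hits": motif_hits,
        "classification": results,
    }

    if len(records) >= 3:
        alignment: Alignment = stage("align", lambda: progressive_align(records))
        if config.extract_regions:
            alignment = stage(
                "extract_regions", lambda: extract_region_columns(alignment, annotations)
            )
        # FASTA of the (possibly region-restricted) alignment, gaps as dashes
        with open(out / "alignment.fasta", "w") as fh:
            for sid, row in alignment.rows.items():
                fh.write(f">{sid}\n{row}\n")
        dm = stage("distances", lambda: poisson_distance(alignment, config.p_cap, config.d_max))
        (out / "distances.phy").write_text(dm.to_phylip())
        tree = stage("bionj", lambda: bionj(dm))
        tree.write(out / "tree.nwk")
        bundle["alignment"] = alignment
        bundle["distances"] = dm
        bundle["tree"] = tree
        if config.clade_file:
            taxa = {
                line.strip()
                for line in Path(config.clade_file).read_text().splitlines()
                if line.strip()
            }
            mono = stage("monophyly", lambda: is_monophyletic(tree, taxa))
            bundle["monophyletic"] = mono
            (out / "monophyly.txt").write_text(
                f"taxa\t{','.join(sorted(taxa))}\nmonophyletic\t{mono}\n"
            )

    manifest = {
        "package": "shspkit",
        "version": __version__,
        "config": asdict(config),
        "n_sequences": len(records),
        "stage_seconds": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle
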