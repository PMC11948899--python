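"""End-to-end orchestration: mapping runs and insertion-evidence runs.

Each run executes the library stages in order, writes tables/JSON next to
an embedded copy of its configuration, and returns a machine-readable
report.  Reports are reproducible from their embedded config: identical
config gives an identical report body.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from . import consequence as cq
from . import junction as jx
from . import scan as sc
from . import variants as va
from .cross import CrossDesign

log = logging.getLogger(__name__)


def _tool_version() -> str:
    try:
        return version("cosegscan")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _write_report(report: dict, out_dir: Path, name: str) -> dict:
    report["tool_version"] = _tool_version()
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / name, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_mapping(config: dict) -> dict:
    """load -> mask -> classify -> combine -> scan -> call (-> refine).

    Config keys: ``vcf``, ``design`` (path or CrossDesign), optional
    ``mask`` BED, ``window``/``step``/``denominator``/``threshold_fraction``,
    optional ``scaffold_lengths``, optional ``sites`` TSV of recombinant
    genotypes, ``out_dir``.
    """
    out_dir = Path(config.get("out_dir", "."))
    design = config["design"]
    if not isinstance(design, CrossDesign):
        design = CrossDesign.from_yaml(design)

    variants = va.load_variants(config["vcf"], design)
    n_loaded = len(variants)
    if config.get("mask"):
        variants = va.apply_repeat_mask(variants, config["mask"])
    n_masked = sum(v.in_repeat for v in variants)
    kept = [v for v in variants if not v.in_repeat]

    verdicts = [va.combine_families(v, design) for v in kept]
    per_family_counts = {
        fam: sum(vd.per_family[fam] for vd in verdicts) for fam in design.family_ids
    }
    n_combined = sum(vd.combined for vd in verdicts)
    log.info(
        "variants loaded=%d masked=%d kept=%d combined-coseg=%d",
        n_loaded, n_masked, len(kept), n_combined,
    )

    denominator = config.get("denominator", "all_variants")
    parental = None
    if denominator == "parental_coseg":
        parental_design = CrossDesign(
            samples=[s for s in design.samples if s.role.value.endswith("parent")],
            orientation=design.orientation,
            missing_policy=design.missing_policy,
        )
        parental = {
            v.key: va.combine_families(v, parental_design).combined for v in kept
        }

    stats = sc.scan_windows(
        verdicts,
        kept,
        window_size=int(config.get("window", sc.WINDOW_SIZE_DEFAULT)),
        step=int(config.get("step", sc.STEP_DEFAULT)),
        denominator_mode=denominator,
        scaffold_lengths=config.get("scaffold_lengths"),
        parental_coseg=parental,
    )
    interval = sc.call_interval(
        stats, verdicts, kept,
        threshold_fraction=float(config.get("threshold_fraction", 0.9)),
    )
    if config.get("sites"):
        calls = sc.read_recombinant_sites(config["sites"])
        interval = sc.refine_with_recombinants(interval, calls, design.orientation)

    out_dir.mkdir(parents=True, exist_ok=True)
    va.cosegregation_table(kept, design).to_csv(
        out_dir / "cosegregation.tsv", sep="\t", index=False
    )
    sc.windows_table(stats).to_csv(out_dir / "windows.tsv", sep="\t", index=False)
    with open(out_dir / "interval.json", "w") as fh:
        json.dump(interval.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    cfg_echo = {k: v for k, v in config.items() if k != "design"}
    cfg_echo["design"] = design.to_dict()
    report = {
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in cfg_echo.items()},
        "counts": {
            "variants_loaded": n_loaded,
            "variants_masked": n_masked,
            "variants_retained": len(kept),
            "coseg_per_family": per_family_counts,
            "coseg_combined": n_combined,
        },
        "interval": interval.to_dict(),
        "denominator_mode": denominator,
    }
    return _write_report(report, out_dir, "mapping_report.json")


def run_insertion_suite(config: dict) -> dict:
    """Junction-read detection plus optional consequence annotation.

    Config keys: ``sam``, ``junction`` = (reference_id, upstream,
    downstream); optional ``wt_cds``/``insert_seq``/``insert_after`` for the
    consequence report; ``start_window``, ``max_softclip``, ``out_dir``.
    """
    out_dir = Path(config.get("out_dir", "."))
    ref_id, up, down = config["junction"]
    model = jx.JunctionModel(str(ref_id), int(up), int(down))
    reads = jx.read_sam(config["sam"], reference_id=model.reference_id)
    hits = jx.detect_junction_reads(
        reads,
        model,
        start_window=tuple(config.get("start_window", jx.START_WINDOW_DEFAULT)),
        max_softclip=int(config.get("max_softclip", jx.MAX_SOFTCLIP_DEFAULT)),
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    jx.hits_table(hits).to_csv(out_dir / "junction_hits.tsv", sep="\t", index=False)

    report = {
        "config": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in config.items()
        },
        "n_reads": len(reads),
        "n_junction_hits": len(hits),
        "insert_length": model.insert_length,
    }
    if config.get("wt_cds"):
        ti = cq.TranscriptInsertion(
            wildtype_cds=config["wt_cds"],
            insert_seq=config["insert_seq"],
            insert_after=int(config["insert_after"]),
        )
        consequence = cq.annotate_consequence(ti)
        with open(out_dir / "consequence.json", "w") as fh:
            json.dump(consequence.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        report["consequence"] = {
            "protein_length": consequence.protein_length,
            "truncated": consequence.truncated,
            "novel_aa_after_junction": consequence.novel_aa_after_junction,
            "stop_loss": consequence.stop_loss,
        }
    return _write_report(report, out_dir, "insertion_report.json")
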