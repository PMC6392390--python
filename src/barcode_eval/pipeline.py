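"""End-to-end barcode-effectiveness pipeline.

Stage order mirrors the evaluation workflow: molecular/morphological
concordance first (specimens flagged incorrect or mislabeled are excluded
from all downstream identification statistics), then the cohort filter to
species with at least two representatives, then — per locus and for the
multi-locus concatenation — distance matrices, best-close-match
identification, barcoding-gap and discrimination statistics, and NJ trees
with bootstrap supports scored for rank-level monophyly. Every artifact is
written under the output directory and hashed into a manifest, so identical
inputs, configuration and seed yield an identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import concordance as conc
from .best_close_match import BCMConfig, best_close_match
from .data_model import (
    LocusAlignment,
    MultiLocusDataset,
    concatenate_loci,
    filter_min_representatives,
    subset_dataset,
    trim_alignment_ends,
)
from .distances import (
    DistanceModelParams,
    distance_matrix,
    partition_divergences,
    welch_t_test,
)
from .gap_discrimination import (
    barcoding_gap_test,
    divergence_histogram,
    species_discrimination,
)
from .phylogeny import (
    MonophylyConfig,
    bootstrap_support,
    monophyly_percent,
    parsimony_search,
    reference_clade_congruence,
    write_newick,
)

logger = logging.getLogger(__name__)

FLAGGED_CATEGORIES = ("incorrect", "mislabeled")


@dataclass
class PipelineConfig:
    loci: list[str] = field(default_factory=lambda: ["matK", "rbcL"])
    model: DistanceModelParams = field(default_factory=DistanceModelParams)
    bcm: BCMConfig = field(default_factory=BCMConfig)
    support_min: float = 70.0
    require_support: bool = True
    bootstrap_replicates: int = 100
    min_representatives: int = 2
    trim_min_coverage: float | None = 0.5  # None disables end trimming
    exclude_flagged: bool = True
    run_parsimony: bool = False
    histogram_bin_width: float = 0.01
    reference_groups: dict[str, list[str]] | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        model = DistanceModelParams(**raw.pop("model", {}))
        bcm = BCMConfig(**raw.pop("bcm", {}))
        return cls(model=model, bcm=bcm, **raw)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default) + "\n")


def _write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def run_concordance_stage(
    ds: MultiLocusDataset, loci: Sequence[str]
) -> tuple[list[conc.ConcordanceResult], set[str]]:
    """Classify every specimen; return results and the flagged specimen ids."""
    results = []
    for s in ds.specimens:
        mol = {loc: s.molecular_by_locus.get(loc) for loc in loci}
        results.append(conc.classify_concordance(s.specimen_id, s.morph, mol))
    flagged = {r.specimen_id for r in results if r.category in FLAGGED_CATEGORIES}
    return results, flagged


def _restrict_to_pairs(aln: LocusAlignment, labels) -> LocusAlignment:
    """Drop members whose species has < 2 sequences in this alignment."""
    counts: dict[str, int] = {}
    for sid in aln.ids:
        sp = labels[sid].species
        counts[sp] = counts.get(sp, 0) + 1
    members = [(sid, seq) for sid, seq in aln.members if counts[labels[sid].species] >= 2]
    return LocusAlignment(aln.locus, members, dict(aln.locus_offsets))


def analyze_alignment(
    aln: LocusAlignment,
    labels,
    cfg: PipelineConfig,
    out: Path,
) -> dict:
    """Distance/BCM/gap/discrimination/tree analyses for one alignment."""
    m = distance_matrix(aln, cfg.model)
    part = partition_divergences(m, labels)
    summary: dict = {"locus": aln.locus, "n_specimens": m.n, "alignment_length": aln.length}

    _write_text(out / "distances.phylip.txt", m.to_phylip())
    m.to_long_table().to_csv(out / "distances.tsv", sep="\t", index=False)

    results, bcm_summary = best_close_match(m, labels, cfg.bcm, partition=part)
    rows = "\n".join(
        "\t".join(
            [
                r.query_id,
                r.category,
                "" if r.min_distance is None else f"{r.min_distance:.8f}",
                ",".join(r.match_ids),
            ]
        )
        for r in results
    )
    _write_text(out / "bcm_queries.tsv", "query_id\tcategory\td_min\tmatch_ids\n" + rows + "\n")
    summary["best_close_match"] = {
        "threshold_T": bcm_summary.threshold_T,
        "n_queries": bcm_summary.n_queries,
        "counts": bcm_summary.counts,
        "percentages": bcm_summary.percentages,
    }

    gap = barcoding_gap_test(part)
    t, df, p = welch_t_test(part.intra_values, part.inter_values)
    gap_doc = dataclasses.asdict(gap)
    gap_doc["welch_t"] = {"t": t, "df": df, "p": p}
    _write_json(out / "gap.json", gap_doc)
    summary["gap"] = gap_doc

    hist = divergence_histogram(part, cfg.histogram_bin_width)
    hist.to_csv(out / "histogram.tsv", sep="\t", index=False)

    disc = species_discrimination(m, labels)
    _write_json(
        out / "discrimination.json",
        {
            "per_species": disc.per_species,
            "unassessable": disc.unassessable,
            "n_discriminated": disc.n_discriminated,
            "n_assessed": disc.n_assessed,
            "percent": disc.percent,
        },
    )
    summary["discrimination"] = {
        "percent": disc.percent,
        "n_discriminated": disc.n_discriminated,
        "n_assessed": disc.n_assessed,
    }

    tree_seed = (cfg.seed + zlib.crc32(aln.locus.encode())) % (2**31)
    tree = bootstrap_support(aln, cfg.model, cfg.bootstrap_replicates, seed=tree_seed)
    _write_text(out / "nj_tree.newick", write_newick(tree))
    summary["monophyly"] = {}
    for rank in ("species", "genus", "family"):
        rep = monophyly_percent(
            tree,
            labels,
            MonophylyConfig(rank=rank, support_min=cfg.support_min, require_support=cfg.require_support),
        )
        _write_json(out / f"monophyly_{rank}.json", dataclasses.asdict(rep))
        summary["monophyly"][rank] = {"NJ": rep.percent}

    if cfg.run_parsimony:
        mp_tree, mp_len = parsimony_search(aln, tree)
        _write_text(out / "mp_tree.newick", write_newick(mp_tree))
        summary["parsimony_length"] = mp_len
        for rank in ("species", "genus", "family"):
            rep = monophyly_percent(
                mp_tree,
                labels,
                MonophylyConfig(rank=rank, support_min=cfg.support_min, require_support=False),
            )
            _write_json(out / f"monophyly_{rank}_mp.json", dataclasses.asdict(rep))
            summary["monophyly"][rank]["MP"] = rep.percent

    if cfg.reference_groups:
        cong = reference_clade_congruence(tree, labels, cfg.reference_groups)
        _write_json(out / "order_congruence.json", cong)
        summary["order_congruence"] = cong
    return summary


def run_pipeline(ds: MultiLocusDataset, cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full evaluation; returns the report (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for locus in cfg.loci:
        if locus not in ds.alignments:
            raise ValueError(f"configured locus {locus!r} not in dataset")

    if cfg.trim_min_coverage is not None:
        ds = MultiLocusDataset(
            specimens=ds.specimens,
            alignments={
                loc: (
                    trim_alignment_ends(aln, cfg.trim_min_coverage)
                    if loc in cfg.loci
                    else aln
                )
                for loc, aln in ds.alignments.items()
            },
        )

    report: dict = {"config": {"loci": list(cfg.loci), "seed": cfg.seed}}

    # Stage 1: concordance and exclusion of flagged barcodes
    results, flagged = run_concordance_stage(ds, cfg.loci)
    assessed = [r for r in results if r.category != "unassessed"]
    if assessed:
        rows = "\n".join(f"{r.specimen_id}\t{r.category}" for r in results)
        _write_text(out / "concordance" / "per_specimen.tsv", "specimen_id\tcategory\n" + rows + "\n")
        summary = conc.summarize_concordance(results)
        _write_json(out / "concordance" / "summary.json", summary)
        report["concordance"] = summary
        report["flagged_excluded"] = sorted(flagged) if cfg.exclude_flagged else []
    else:
        logger.info("no molecular labels present; concordance stage skipped")
        flagged = set()

    if cfg.exclude_flagged and flagged:
        ds = subset_dataset(ds, [i for i in ds.specimen_ids if i not in flagged])

    # Stage 2: cohort filter
    ds = filter_min_representatives(ds, k=cfg.min_representatives)
    labels = ds.labels()
    report["n_specimens_analyzed"] = len(ds.specimens)

    # Stage 3: per-locus and concatenated analyses
    report["analyses"] = {}
    for locus in cfg.loci:
        aln = _restrict_to_pairs(ds.alignments[locus], labels)
        report["analyses"][locus] = analyze_alignment(aln, labels, cfg, out / locus)
    if len(cfg.loci) > 1:
        concat = _restrict_to_pairs(concatenate_loci(ds, cfg.loci), labels)
        report["analyses"][concat.locus] = analyze_alignment(
            concat, labels, cfg, out / concat.locus.replace("+", "_")
        )

    _write_json(out / "report.json", report)
    _write_text(out / "report.md", render_report_markdown(report))

    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(out))] = hashlib.sha256(path.read_bytes()).hexdigest()
    _write_json(out / "manifest.json", manifest)
    return report


def render_report_markdown(report: Mapping) -> str:
    """Compact Markdown summary: identification success, gap, monophyly."""
    lines = ["# Barcode effectiveness report", ""]
    analyses = report.get("analyses", {})
    lines += [
        "## Best-close-match identification (% of queries)",
        "",
        "| Barcode | correct | ambiguous | incorrect | unidentified | T |",
        "|---|---|---|---|---|---|",
    ]
    for locus, a in analyses.items():
        pc = a["best_close_match"]["percentages"]
        T = a["best_close_match"]["threshold_T"]
        lines.append(
            f"| {locus} | {pc['correct']:.1f} | {pc['ambiguous']:.1f} | "
            f"{pc['incorrect']:.1f} | {pc['unidentified']:.1f} | {T:.4f} |"
        )
    lines += [
        "",
        "## Divergences and discrimination",
        "",
        "| Barcode | mean intra | mean inter | gap present | discriminated (%) |",
        "|---|---|---|---|---|",
    ]
    for locus, a in analyses.items():
        g = a["gap"]
        lines.append(
            f"| {locus} | {g['mean_intra']:.4f} | {g['mean_inter']:.4f} | "
            f"{g['gap_present']} | {a['discrimination']['percent']:.1f} |"
        )
    lines += [
        "",
        "## Monophyletic clades (%, by rank and method)",
        "",
        "| Barcode | Method | Family | Genus | Species |",
        "|---|---|---|---|---|",
    ]
    for locus, a in analyses.items():
        methods = sorted({m for rank in a["monophyly"].values() for m in rank})
        for method in methods:
            vals = [
                f"{a['monophyly'][rank].get(method, float('nan')):.1f}"
                for rank in ("family", "genus", "species")
            ]
            lines.append(f"| {locus} | {method} | {vals[0]} | {vals[1]} | {vals[2]} |")
    return "\n".join(lines) + "\n"
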