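"""End-to-end orchestration of the five pipeline stages.

catalog parse → site anchoring → gene resolution → ortholog expansion →
alignment + window conservation, followed by report/summary emission.  The
pipeline is deterministic: re-running the same configuration byte-reproduces all
outputs.  A machine-parseable funnel (``key=value`` lines) records how many
records survive each stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from . import alignment as _alignment
from . import conservation as _conservation
from . import formats_io as fio
from . import ortholog_map as omap
from . import site_anchor as anchor
from .site_anchor import AnchoredSite
from .synthetic_fixtures import validated_pairs

logger = logging.getLogger("cesa")

__all__ = ["RunConfig", "RunResult", "run", "run_validated_pairs", "SUMMARY_COLUMNS"]

SUMMARY_COLUMNS = ["cutoff", "n_sites", "n_source_genes", "n_target_genes"]


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run (all paths plus options)."""

    catalog: str = ""
    source_organisms: tuple[str, ...] = ("human", "mouse", "rat")
    target_organism: str = "fly"
    source_fasta: str = ""
    target_fasta: str = ""
    source_protein_gene: str = ""
    target_protein_gene: str = ""
    ortholog_table: str = ""
    alias_tables: tuple[str, ...] = ()
    min_rank: str = "moderate"
    require_antibody: bool = True
    cutoffs: tuple[int, ...] = _conservation.DEFAULT_CUTOFFS
    allow_conservative: bool = True
    similarity_scheme: str = "physicochemical"
    isoform_mode: str = "all"
    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    peptide_only: bool = False
    report_path: str = "report.tsv"
    summary_path: str = "summary.tsv"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise fio.FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("source_organisms", "alias_tables", "cutoffs"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self) -> str:
        data = {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }
        return yaml.safe_dump(data, sort_keys=False)


@dataclass
class RunResult:
    results: list[_conservation.ConservationResult]
    funnel: dict[str, int]
    skip_tally: dict[str, int]
    anchor_tally: dict[str, int]
    summary: list[tuple[int, int, int, int]]  # (cutoff, sites, source genes, target genes)


def _check_inputs(config: RunConfig) -> None:
    needed = [
        config.catalog,
        config.ortholog_table,
        config.target_fasta,
        config.target_protein_gene,
    ]
    if not config.peptide_only:
        needed += [config.source_fasta, config.source_protein_gene]
    needed += list(config.alias_tables)
    for path in needed:
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"input not readable: {path!r}")


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the report and summary files."""
    _check_inputs(config)
    groups = _conservation.similarity_scheme(config.similarity_scheme)
    scheme = _alignment.default_scheme(config.matrix_name)
    if (config.gap_open, config.gap_extend) != (scheme.gap_open, scheme.gap_extend):
        scheme = replace(scheme, gap_open=config.gap_open, gap_extend=config.gap_extend)

    records, skip_tally = fio.read_phosphosite_catalog(
        config.catalog, config.source_organisms, config.require_antibody
    )
    funnel = {"records_read": len(records)}

    alias_maps = [fio.read_gene_map(p) for p in config.alias_tables]
    tgt_proteins = fio.build_protein_records(
        fio.read_fasta(config.target_fasta),
        fio.read_protein_gene_table(config.target_protein_gene),
        default_organism=config.target_organism,
    )
    target_index = omap.GeneIndex.build(tgt_proteins)

    if config.peptide_only:
        # each catalog peptide stands in for its own source protein
        anchored_sites, anchor_tally = [], {}
        for rec in records:
            core, offset = anchor.unpad_flank(rec.flank_peptide)
            protein = fio.ProteinRecord(
                rec.protein_accession, "", rec.gene_symbol, rec.organism, core
            )
            anchored_sites.append(
                AnchoredSite(rec, protein, offset + 1, "direct", core, offset)
            )
        source_index = omap.GeneIndex.build((), alias_maps)
    else:
        src_proteins = fio.build_protein_records(
            fio.read_fasta(config.source_fasta),
            fio.read_protein_gene_table(config.source_protein_gene),
        )
        proteome = anchor.ProteomeIndex(src_proteins)
        anchored_sites, anchor_tally = anchor.anchor_all(records, proteome)
        source_index = omap.GeneIndex.build(src_proteins, alias_maps)
    funnel["records_anchored"] = len(anchored_sites)

    pairs = fio.read_ortholog_table(config.ortholog_table, config.min_rank)

    resolved: list[tuple[AnchoredSite, str]] = []
    for site in anchored_sites:
        gene = omap.resolve_gene(site.record, source_index)
        if isinstance(gene, str):
            resolved.append((site, gene))
    funnel["sites_gene_resolved"] = len(resolved)
    funnel["source_genes_resolved"] = len({g for _, g in resolved})

    mapped: list[tuple[AnchoredSite, str, str]] = []
    for site, gene in resolved:
        for tgt_gene in omap.orthologs_of(gene, pairs, config.min_rank):
            mapped.append((site, gene, tgt_gene))
    funnel["sites_ortholog_mapped"] = len({id(s) for s, _, _ in mapped})
    funnel["target_genes_mapped"] = len({t for _, _, t in mapped})

    aln_cache: dict[tuple[str, str], _alignment.AlignmentResult] = {}
    results: list[_conservation.ConservationResult] = []
    for site, _, tgt_gene in mapped:
        for isoform in omap.select_isoforms(tgt_gene, target_index, config.isoform_mode):
            key = (site.protein.accession + "\x00" + site.protein.sequence, isoform.accession)
            aln = aln_cache.get(key)
            if aln is None:
                aln = _alignment.global_align(
                    site.protein.sequence,
                    isoform.sequence,
                    scheme,
                    source_accession=site.protein.accession,
                    target_accession=isoform.accession,
                )
                aln_cache[key] = aln
            results.append(
                _conservation.evaluate_site(
                    aln,
                    site,
                    isoform,
                    cutoffs=config.cutoffs,
                    groups=groups,
                    allow_conservative=config.allow_conservative,
                )
            )
    funnel["alignments"] = len(aln_cache)
    funnel["result_rows"] = len(results)

    summary = []
    for L in sorted(config.cutoffs):
        n_sites, n_src, n_tgt = _conservation.summarize(results, L)
        summary.append((L, n_sites, n_src, n_tgt))
    min_cutoff = min(config.cutoffs) if config.cutoffs else 6
    funnel["sites_qualifying_at_min_cutoff"] = next(
        (s for (L, s, _, _) in summary if L == min_cutoff), 0
    )

    with open(config.report_path, "w", encoding="utf-8") as fh:
        fio.write_report(results, fh)
    with open(config.summary_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for row in summary:
            fh.write("\t".join(str(v) for v in row) + "\n")

    if not anchored_sites:
        logger.warning("zero anchored sites; report is empty")
    for key, value in {**funnel, **{f"skip_{k}": v for k, v in skip_tally.items()},
                       **{f"anchor_fail_{k}": v for k, v in anchor_tally.items()}}.items():
        logger.info("%s=%d", key, value)

    return RunResult(results, funnel, dict(skip_tally), dict(anchor_tally), summary)


def run_validated_pairs(
    allow_conservative: bool = True,
) -> list[dict]:
    """Evaluate the golden set of 12 validated epitope pairs peptide-vs-peptide.

    Each 15-mer pair is globally aligned and scored exactly as a full protein
    pair would be; rows report the contiguous identity run and best qualifying
    window lengths next to the known conserved-region length.
    """
    rows = []
    for human_gene, fly_gene, human_pep, fly_pep, known_run in validated_pairs(
        with_genes=True
    ):
        record = fio.PhosphoSiteRecord(
            gene_symbol=human_gene,
            protein_accession=f"{human_gene}_pep",
            organism="human",
            residue=human_pep[7] if human_pep[7] in "STY" else "S",
            position=8,
            flank_peptide=human_pep,
            antibody_ids=("validated",),
            site_label=f"{human_pep[7]}8-p",
            center_mismatch=human_pep[7] not in "STY",
        )
        protein = fio.ProteinRecord(record.protein_accession, "", human_gene, "human", human_pep)
        target = fio.ProteinRecord(f"{fly_gene}_pep", "", fly_gene, "fly", fly_pep)
        anchored = AnchoredSite(record, protein, 8, "direct", human_pep, 7)
        aln = _alignment.global_align(
            human_pep, fly_pep,
            source_accession=protein.accession, target_accession=target.accession,
        )
        result = _conservation.evaluate_site(
            aln, anchored, target, allow_conservative=allow_conservative
        )
        rows.append(
            {
                "source_gene": human_gene,
                "target_gene": fly_gene,
                "source_peptide": human_pep,
                "target_peptide": fly_pep,
                "known_run": known_run,
                "identity_run": result.identity_run,
                "best_strict": result.best_strict,
                "best_relaxed": result.best_relaxed,
            }
        )
    return rows
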