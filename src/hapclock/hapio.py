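"""Readers and writers for panels, annotations, maps, alignments and results.

Supported phased-panel dialects
-------------------------------
``tsv``
    One row per chromosome: ``sample_id  hap_index  population`` followed by
    one column per site id, values ``0``/``1``/``.`` already coded against
    the ancestral state.
``vcf``
    Plain-text phased VCF (v4.x, GT separated by ``|``).  REF/ALT letters are
    recoded to 0/1 against the site annotation's ancestral allele; without an
    annotation, REF is taken as ancestral.
``impute``
    An IMPUTE-style triple ``prefix.haps`` / ``prefix.legend`` /
    ``prefix.sample``.  The legend carries ``id position a0 a1`` (header
    line included); the haps file holds the site-by-chromosome 0/1 matrix
    (``?`` for missing); the sample file has the usual two header lines and
    one row per individual with an optional ``population`` column.

All coordinates are 1-based inclusive; VCF positions are already 1-based so
no conversion is applied.  Multiallelic records are rejected: the analysis
is strictly biallelic.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .classify import HaplotypeDefinitionTable
from .types import (
    MISSING,
    HapclockError,
    PairwiseAlignment,
    PhasedPanel,
    RecombinationMap,
    SiteAnnotation,
)

# ---------------------------------------------------------------------------
# site annotations


def read_site_annotation(path: str | os.PathLike) -> list[SiteAnnotation]:
    """Read a site-annotation TSV.

    Columns: ``site_id  position  ancestral  derived`` and optionally
    ``nickname`` and ``kind``.  Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"site_id", "position", "ancestral", "derived"}
    missing = required - set(df.columns)
    if missing:
        raise HapclockError(f"annotation file lacks columns {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        nickname = getattr(row, "nickname", None)
        if nickname is not None and (pd.isna(nickname) or nickname == ""):
            nickname = None
        kind = getattr(row, "kind", "SNP")
        if kind is None or pd.isna(kind):
            kind = "SNP"
        sites.append(
            SiteAnnotation(
                site_id=row.site_id,
                position=int(row.position),
                ancestral_allele=row.ancestral,
                derived_allele=row.derived,
                nickname=nickname,
                kind=kind,
            )
        )
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise HapclockError("duplicate site_id in annotation file")
    return sites


def write_site_annotation(sites: Sequence[SiteAnnotation], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "position": [s.position for s in sites],
            "ancestral": [s.ancestral_allele for s in sites],
            "derived": [s.derived_allele for s in sites],
            "nickname": [s.nickname or "" for s in sites],
            "kind": [s.kind for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _synthetic_annotation(
    site_ids: Sequence[str], positions: Sequence[int]
) -> list[SiteAnnotation]:
    return [
        SiteAnnotation(site_id=i, position=p, ancestral_allele="A", derived_allele="G")
        for i, p in zip(site_ids, positions)
    ]


# ---------------------------------------------------------------------------
# phased panels

DIALECTS = ("tsv", "vcf", "impute")
_META_COLS = ("sample_id", "hap_index", "population")


def read_phased_panel(
    path: str | os.PathLike,
    dialect: str,
    annotation: Sequence[SiteAnnotation] | None = None,
    populations: Mapping[str, str] | None = None,
) -> PhasedPanel:
    """Read a phased panel, recoding alleles to 0/1/MISSING against the annotation.

    ``populations`` maps sample id -> population label for dialects that do
    not carry population information themselves (VCF, and IMPUTE files
    without a population column); unmapped samples get ``"NA"``.
    """
    if dialect == "tsv":
        return _read_tsv_panel(path, annotation)
    if dialect == "vcf":
        return _read_vcf_panel(path, annotation, populations)
    if dialect == "impute":
        return _read_impute_panel(path, annotation, populations)
    raise HapclockError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_phased_panel(
    panel: PhasedPanel, path: str | os.PathLike, dialect: str, contig: str = "15"
) -> None:
    """Write a panel in any supported dialect (inverse of read_phased_panel)."""
    if dialect == "tsv":
        _write_tsv_panel(panel, path)
    elif dialect == "vcf":
        _write_vcf_panel(panel, path, contig)
    elif dialect == "impute":
        _write_impute_panel(panel, path)
    else:
        raise HapclockError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _read_tsv_panel(
    path: str | os.PathLike, annotation: Sequence[SiteAnnotation] | None
) -> PhasedPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _META_COLS:
        if col not in df.columns:
            raise HapclockError(f"TSV panel lacks column {col!r}")
    site_ids = [c for c in df.columns if c not in _META_COLS]
    if len(set(site_ids)) != len(site_ids):
        raise HapclockError("duplicate site_id column in TSV panel")
    sites = _resolve_annotation(site_ids, annotation)
    codes = np.full((len(df), len(site_ids)), MISSING, dtype=np.int8)
    for j, sid in enumerate(site_ids):
        col = df[sid].to_numpy()
        for i, v in enumerate(col):
            if v in ("0", "1"):
                codes[i, j] = int(v)
            elif v in (".", "", "nan") or pd.isna(v):
                codes[i, j] = MISSING
            else:
                raise HapclockError(
                    f"sample {df['sample_id'][i]} site {sid}: allele code {v!r} "
                    "not 0/1/."
                )
    return PhasedPanel(
        sites=sites,
        chrom_ids=[(s, int(h)) for s, h in zip(df["sample_id"], df["hap_index"])],
        populations=list(df["population"]),
        alleles=codes,
    )


def _write_tsv_panel(panel: PhasedPanel, path: str | os.PathLike) -> None:
    data = {
        "sample_id": [s for s, _ in panel.chrom_ids],
        "hap_index": [h for _, h in panel.chrom_ids],
        "population": panel.populations,
    }
    for j, site in enumerate(panel.sites):
        col = panel.alleles[:, j]
        data[site.site_id] = ["." if a == MISSING else str(int(a)) for a in col]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _resolve_annotation(
    site_ids: Sequence[str], annotation: Sequence[SiteAnnotation] | None
) -> list[SiteAnnotation]:
    if annotation is None:
        return _synthetic_annotation(site_ids, range(1, len(site_ids) + 1))
    by_id = {s.site_id: s for s in annotation}
    missing = [i for i in site_ids if i not in by_id]
    if missing:
        raise HapclockError(f"annotation lacks sites {missing}")
    return [by_id[i] for i in site_ids]


def _read_vcf_panel(
    path: str | os.PathLike,
    annotation: Sequence[SiteAnnotation] | None,
    populations: Mapping[str, str] | None,
) -> PhasedPanel:
    by_pos = {s.position: s for s in annotation} if annotation is not None else None
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        sites: list[SiteAnnotation] = []
        columns: list[np.ndarray] = []
        seen_ids: set[str] = set()
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise HapclockError(
                    f"site {rec.id or rec.pos}: multiallelic or monomorphic records "
                    "are not supported"
                )
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if by_pos is not None:
                try:
                    site = by_pos[rec.pos]
                except KeyError:
                    raise HapclockError(f"no annotation for VCF position {rec.pos}")
                alleles = {ref, alt}
                expected = {site.ancestral_allele, site.derived_allele}
                if site.ancestral_known and alleles != expected:
                    raise HapclockError(
                        f"site {site.site_id}: VCF alleles {sorted(alleles)} do not "
                        f"match annotation {sorted(expected)}"
                    )
                anc_is_ref = site.ancestral_allele == ref or not site.ancestral_known
            else:
                site = SiteAnnotation(
                    site_id=rec.id or f"site{rec.pos}",
                    position=rec.pos,
                    ancestral_allele=ref,
                    derived_allele=alt,
                )
                anc_is_ref = True
            if site.site_id in seen_ids:
                raise HapclockError(f"duplicate site_id {site.site_id} in VCF")
            seen_ids.add(site.site_id)
            col = np.full(2 * len(samples), MISSING, dtype=np.int8)
            for si, sample in enumerate(samples):
                call = rec.samples[sample]
                gt = call["GT"]
                if gt is None or len(gt) != 2:
                    raise HapclockError(
                        f"sample {sample} site {site.site_id}: diploid GT required"
                    )
                if not call.phased and None not in gt and gt[0] != gt[1]:
                    raise HapclockError(
                        f"sample {sample} site {site.site_id}: unphased heterozygote"
                    )
                for h, g in enumerate(gt):
                    if g is None:
                        continue
                    derived = (g == 1) if anc_is_ref else (g == 0)
                    col[2 * si + h] = 1 if derived else 0
            sites.append(site)
            columns.append(col)
    if not sites:
        raise HapclockError("VCF contains no usable records")
    order = np.argsort([s.position for s in sites], kind="stable")
    sites = [sites[k] for k in order]
    alleles = np.stack([columns[k] for k in order], axis=1)
    chrom_ids = [(s, h) for s in samples for h in (0, 1)]
    pops = [(populations or {}).get(s, "NA") for s, _ in chrom_ids]
    return PhasedPanel(sites=sites, chrom_ids=chrom_ids, populations=pops, alleles=alleles)


def _write_vcf_panel(panel: PhasedPanel, path: str | os.PathLike, contig: str) -> None:
    # Chromosomes are paired back into diploid samples; an odd haplotype
    # (unpaired hap_index) is an error because VCF GT fields are diploid here.
    samples: list[str] = []
    index: dict[str, dict[int, int]] = {}
    for i, (sample, hap) in enumerate(panel.chrom_ids):
        index.setdefault(sample, {})[hap] = i
        if sample not in samples:
            samples.append(sample)
    for sample, haps in index.items():
        if sorted(haps) != [0, 1]:
            raise HapclockError(
                f"sample {sample}: VCF export needs haplotype indices 0 and 1"
            )
    maxpos = panel.sites[-1].position
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={maxpos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, site in enumerate(panel.sites):
            ref, alt = site.ancestral_allele, site.derived_allele
            if not site.ancestral_known:
                ref, alt = site.derived_allele, "N"  # arbitrary but fixed coding
            cells = []
            for sample in samples:
                a = panel.alleles[index[sample][0], j]
                b = panel.alleles[index[sample][1], j]
                cells.append(
                    "|".join("." if x == MISSING else str(int(x)) for x in (a, b))
                )
            fh.write(
                f"{contig}\t{site.position}\t{site.site_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def _impute_paths(prefix: str | os.PathLike) -> tuple[str, str, str]:
    p = os.fspath(prefix)
    return p + ".haps", p + ".legend", p + ".sample"


def _read_impute_panel(
    prefix: str | os.PathLike,
    annotation: Sequence[SiteAnnotation] | None,
    populations: Mapping[str, str] | None,
) -> PhasedPanel:
    haps_path, legend_path, sample_path = _impute_paths(prefix)
    legend = pd.read_csv(legend_path, sep=r"\s+", dtype=str)
    for col in ("id", "position", "a0", "a1"):
        if col not in legend.columns:
            raise HapclockError(f"legend file lacks column {col!r}")
    if legend["id"].duplicated().any():
        dup = legend["id"][legend["id"].duplicated()].iloc[0]
        raise HapclockError(f"duplicate site_id {dup} in legend")

    with open(sample_path) as fh:
        header = fh.readline().split()
        fh.readline()  # type line ("0 0 0 ...")
        rows = [line.split() for line in fh if line.strip()]
    sample_ids = [r[1] for r in rows]
    pop_col = header.index("population") if "population" in header else None
    sample_pops = {
        r[1]: (r[pop_col] if pop_col is not None else (populations or {}).get(r[1], "NA"))
        for r in rows
    }

    raw = np.loadtxt(haps_path, dtype=str, ndmin=2)
    if raw.shape[0] != len(legend):
        raise HapclockError(
            f"haps file has {raw.shape[0]} rows but legend has {len(legend)} sites"
        )
    if raw.shape[1] != 2 * len(sample_ids):
        raise HapclockError(
            f"haps file has {raw.shape[1]} haplotype columns but sample file "
            f"lists {len(sample_ids)} individuals"
        )

    by_id = {s.site_id: s for s in annotation} if annotation is not None else None
    sites: list[SiteAnnotation] = []
    flip = np.zeros(len(legend), dtype=bool)
    for k, row in enumerate(legend.itertuples(index=False)):
        if by_id is not None:
            try:
                site = by_id[row.id]
            except KeyError:
                raise HapclockError(f"no annotation for legend site {row.id}")
            alleles = {row.a0, row.a1}
            expected = {site.ancestral_allele, site.derived_allele}
            if site.ancestral_known and alleles != expected:
                raise HapclockError(
                    f"site {row.id}: legend alleles {sorted(alleles)} do not match "
                    f"annotation {sorted(expected)}"
                )
            flip[k] = site.ancestral_known and site.ancestral_allele == row.a1
        else:
            site = SiteAnnotation(
                site_id=row.id,
                position=int(row.position),
                ancestral_allele=row.a0,
                derived_allele=row.a1,
            )
        sites.append(site)

    codes = np.full(raw.shape, MISSING, dtype=np.int8)
    codes[raw == "0"] = 0
    codes[raw == "1"] = 1
    unknown = ~np.isin(raw, ("0", "1", "?"))
    if unknown.any():
        k, c = np.argwhere(unknown)[0]
        raise HapclockError(
            f"haps file: allele code {raw[k, c]!r} at site {sites[k].site_id} "
            "(expected 0, 1 or ?)"
        )
    for k in np.where(flip)[0]:
        row = codes[k]
        row[row == 0] = 2
        row[row == 1] = 0
        row[row == 2] = 1

    order = np.argsort([s.position for s in sites], kind="stable")
    sites = [sites[k] for k in order]
    alleles = codes[order].T
    chrom_ids = [(s, h) for s in sample_ids for h in (0, 1)]
    pops = [sample_pops[s] for s, _ in chrom_ids]
    return PhasedPanel(sites=sites, chrom_ids=chrom_ids, populations=pops, alleles=alleles)


def _write_impute_panel(panel: PhasedPanel, prefix: str | os.PathLike) -> None:
    haps_path, legend_path, sample_path = _impute_paths(prefix)
    samples: list[str] = []
    index: dict[str, dict[int, int]] = {}
    pops: dict[str, str] = {}
    for i, (sample, hap) in enumerate(panel.chrom_ids):
        index.setdefault(sample, {})[hap] = i
        pops[sample] = panel.populations[i]
        if sample not in samples:
            samples.append(sample)
    for sample, haps in index.items():
        if sorted(haps) != [0, 1]:
            raise HapclockError(
                f"sample {sample}: IMPUTE export needs haplotype indices 0 and 1"
            )
    with open(legend_path, "w") as fh:
        fh.write("id position a0 a1\n")
        for site in panel.sites:
            anc = site.ancestral_allele if site.ancestral_known else site.derived_allele
            der = site.derived_allele if site.ancestral_known else "N"
            fh.write(f"{site.site_id} {site.position} {anc} {der}\n")
    with open(haps_path, "w") as fh:
        for j in range(panel.n_sites):
            cells = []
            for sample in samples:
                for h in (0, 1):
                    a = panel.alleles[index[sample][h], j]
                    cells.append("?" if a == MISSING else str(int(a)))
            fh.write(" ".join(cells) + "\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing population\n0 0 0 D\n")
        for sample in samples:
            fh.write(f"{sample} {sample} 0 {pops[sample]}\n")


# ---------------------------------------------------------------------------
# haplotype definitions


def read_haplotype_definitions(
    path: str | os.PathLike,
    site_universe: Sequence[str],
    key_site: str = "c11",
    common_freq_threshold: float = 0.005,
) -> HaplotypeDefinitionTable:
    """Read a haplotype-definition TSV: ``name<TAB>derived_sites``.

    ``derived_sites`` is a comma-separated list of site nicknames carrying
    the derived allele; the all-ancestral haplotype has an empty field.
    """
    entries: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["name", "derived_sites"]:
            raise HapclockError(
                "definition file must have columns 'name' and 'derived_sites'"
            )
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[0]
            field = parts[1] if len(parts) > 1 else ""
            if name in entries:
                raise HapclockError(f"duplicate haplotype name {name}")
            derived = frozenset(x for x in field.split(",") if x)
            entries[name] = derived
    return HaplotypeDefinitionTable(
        entries=entries,
        site_universe=tuple(site_universe),
        key_site=key_site,
        common_freq_threshold=common_freq_threshold,
    )


# ---------------------------------------------------------------------------
# recombination maps and alignments


def read_recombination_map(path: str | os.PathLike) -> RecombinationMap:
    """Read a TSV with columns ``start  end  rate_cM_Mb`` (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("start", "end", "rate_cM_Mb"):
        if col not in df.columns:
            raise HapclockError(f"recombination map lacks column {col!r}")
    intervals = [
        (int(r.start), int(r.end), float(r.rate_cM_Mb)) for r in df.itertuples()
    ]
    return RecombinationMap(intervals=intervals)


def read_pairwise_alignment(path: str | os.PathLike) -> PairwiseAlignment:
    """Read a two-sequence gapped FASTA alignment."""
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if len(records) != 2:
        raise HapclockError(
            f"alignment FASTA must contain exactly 2 sequences, found {len(records)}"
        )
    return PairwiseAlignment(seq_a=str(records[0].seq), seq_b=str(records[1].seq))


# ---------------------------------------------------------------------------
# result tables and networks


def network_to_dot(network) -> str:
    """Render a HaplotypeNetwork as Graphviz DOT (deterministic node order)."""
    lines = ["graph haplotypes {"]
    graph = network.graph
    for node in sorted(graph.nodes):
        attrs = graph.nodes[node]
        label = attrs.get("name") or node
        shape = "doublecircle" if node == network.root else "circle"
        style = "solid" if attrs.get("displayed", True) else "dashed"
        lines.append(
            f'  "{node}" [label="{label}\\n{attrs["count"]}", shape={shape}, '
            f"style={style}];"
        )
    for a, b in sorted(graph.edges):
        sites = ",".join(sorted(graph.edges[a, b]["sites"]))
        lines.append(f'  "{a}" -- "{b}" [label="{sites}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_tables(result, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write a tabular or graph result.

    * DataFrames are written as TSV in their existing (deterministic) row
      and column order, with the index when it is named.
    * HaplotypeNetwork objects are written as DOT (``format="dot"``), with
      nodes and edges in sorted order.
    """
    from .hapnetwork import HaplotypeNetwork  # local import avoids a cycle

    if format == "dot":
        if not isinstance(result, HaplotypeNetwork):
            raise HapclockError("DOT export is only defined for haplotype networks")
        with open(path, "w") as fh:
            fh.write(network_to_dot(result))
        return
    if format != "tsv":
        raise HapclockError(f"unknown output format {format!r}")
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, sep="\t", index=result.index.name is not None)
    elif isinstance(result, pd.Series):
        result.to_frame().to_csv(path, sep="\t")
    else:
        raise HapclockError(f"cannot write result of type {type(result).__name__}")
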