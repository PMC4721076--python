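"""Reading and writing genotype tables.

Two on-disk dialects are supported:

* ``cpnssr_csv`` — the package's own CSV layout carrying both marker
  classes: header ``id,sample,cp_hap,<locus1>,<locus2>,...``, one
  individual per row, nuclear cells ``a/b``, missing ``NA``.
* ``genepop`` — the classic GenePop text format (3-digit allele coding),
  nuclear loci only; provided for interchange with other software.

Missing sentinels accepted on input: ``NA``, empty, ``0``/``000``.
Individuals missing every locus are rejected at load.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .markers import (
    MISSING,
    MISSING_TOKENS,
    MarkerPanel,
    MultilocusGenotype,
    SampleTable,
    canonical_pair,
    normalize_allele,
)


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed; names the offending line."""


def read_genotypes(path, format: str = "cpnssr_csv", label: Optional[str] = None):
    """Read a genotype file.

    Returns ``(SampleTable, MarkerPanel)`` with alphabets built from the
    observed data. For ``genepop`` only nuclear loci are populated.
    """
    path = Path(path)
    if format == "cpnssr_csv":
        return _read_cpnssr_csv(path, label)
    if format == "genepop":
        return _read_genepop(path, label)
    raise ValueError(f"unknown format {format!r}")


def _read_cpnssr_csv(path: Path, label: Optional[str]):
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["id", "sample", "cp_hap"]
    if list(df.columns[:3]) != required:
        raise GenotypeParseError(
            f"{path}: header must start with 'id,sample,cp_hap', got {list(df.columns[:3])}"
        )
    loci = list(df.columns[3:])
    genotypes = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        cp = row.cp_hap.strip()
        cp_hap = None if cp in MISSING_TOKENS else cp
        nuclear = {}
        for locus, cell in zip(loci, tuple(row)[3:]):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                nuclear[locus] = None
                continue
            parts = cell.split("/")
            if len(parts) != 2:
                raise GenotypeParseError(
                    f"{path}: line {row_no}, locus {locus}: bad genotype cell {cell!r}"
                )
            pair = canonical_pair(*parts)
            nuclear[locus] = pair
        genotypes.append(MultilocusGenotype(row.id, cp_hap, nuclear))
    tbl_label = label or (df["sample"].iloc[0] if len(df) else "sample")
    table = SampleTable(label=tbl_label, genotypes=genotypes)
    panel = table.marker_panel()
    panel.validate()
    return table, panel


def write_cpnssr_csv(table: SampleTable, path, loci: Optional[Sequence[str]] = None) -> None:
    loci = list(loci) if loci is not None else table.loci()
    rows = []
    for g in table.genotypes:
        row = {"id": g.individual_id, "sample": table.label,
               "cp_hap": g.cp_haplotype if g.cp_haplotype is not None else MISSING}
        for locus in loci:
            pair = g.nuclear_genotypes.get(locus)
            row[locus] = MISSING if pair is None else f"{pair[0]}/{pair[1]}"
        rows.append(row)
    pd.DataFrame(rows, columns=["id", "sample", "cp_hap", *loci]).to_csv(path, index=False)


_GENEPOP_SEP = re.compile(r"[,\s]+")


def _read_genepop(path: Path, label: Optional[str]):
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    # line 1 is a free-text title
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names: one per line, or comma-separated on one line
        loci.extend(x for x in _GENEPOP_SEP.split(lines[i].strip()) if x)
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"{path}: no 'Pop' line found")
    genotypes = []
    pop_idx = 0
    for line_no in range(i, len(lines)):
        raw = lines[line_no].strip()
        if not raw:
            continue
        if raw.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in raw:
            raise GenotypeParseError(f"{path}: line {line_no + 1}: missing ',' after id")
        ind_id, geno_part = raw.split(",", 1)
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise GenotypeParseError(
                f"{path}: line {line_no + 1}: expected {len(loci)} loci, got {len(codes)}"
            )
        nuclear = {}
        for locus, code in zip(loci, codes):
            if not code.isdigit() or len(code) not in (4, 6):
                raise GenotypeParseError(
                    f"{path}: line {line_no + 1}, locus {locus}: bad allele code {code!r}"
                )
            half = len(code) // 2
            nuclear[locus] = canonical_pair(code[:half], code[half:])
        genotypes.append(MultilocusGenotype(ind_id.strip(), None, nuclear))
    table = SampleTable(label=label or "pop1", genotypes=genotypes)
    panel = table.marker_panel()
    panel.validate()
    return table, panel


def write_genepop(table: SampleTable, path, title: str = "exoflow export") -> None:
    """Write nuclear loci in 3-digit GenePop coding (cp haplotypes dropped)."""
    loci = table.loci()
    out = [title]
    out.extend(loci)
    out.append("Pop")
    for g in table.genotypes:
        codes = []
        for locus in loci:
            pair = g.nuclear_genotypes.get(locus)
            if pair is None:
                codes.append("000000")
            else:
                a, b = (int(x) for x in pair)
                if a > 999 or b > 999:
                    raise ValueError(f"allele label too large for 3-digit coding: {pair}")
                codes.append(f"{a:03d}{b:03d}")
        out.append(f"{g.individual_id}, " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


def build_cp_haplotypes(fragment_table: pd.DataFrame, id_col: str = "id") -> dict[str, Optional[str]]:
    """Collapse per-individual cpSSR fragment sizes into haplotype labels.

    The chloroplast genome does not recombine, so the ordered combination of
    fragment sizes is the unit of analysis. The label is the underscore-join
    of the sizes in column order; any missing fragment makes the whole
    haplotype missing.
    """
    frag_cols = [c for c in fragment_table.columns if c != id_col]
    haplotypes: dict[str, Optional[str]] = {}
    for _, row in fragment_table.iterrows():
        sizes = [normalize_allele(row[c]) for c in frag_cols]
        haplotypes[str(row[id_col])] = None if any(s is None for s in sizes) else "_".join(sizes)  # type: ignore[arg-type]
    return haplotypes


def attach_cp_haplotypes(table: SampleTable, haplotypes: dict[str, Optional[str]]) -> SampleTable:
    """Return a copy of ``table`` with cp haplotypes set from a fragment call."""
    genos = [
        MultilocusGenotype(g.individual_id, haplotypes.get(g.individual_id), dict(g.nuclear_genotypes))
        for g in table.genotypes
    ]
    return SampleTable(table.label, genos, stage=table.stage, cross_labels=table.cross_labels)
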