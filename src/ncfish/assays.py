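"""Table-based molecular assays: qPCR Ct arithmetic and oligo validation.

Ct (cycle threshold) tables hold replicate Ct values per gene and cellular
fraction. Delta-Ct between two fractions measures relative abundance
(one cycle = one twofold difference; lower Ct = more template); the
2^-ddCt method normalizes a target gene's fraction enrichment to a
reference gene (Actb by default). Count tables hold normalized RNA-seq
counts per gene and compartment for neurite-to-soma ratios. The oligo
tables published with the study (primers, smiFISH probes, ASOs) ship as
CSV fixtures and can be validated for set size, length, alphabet and
duplicates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "load_probe_table",
    "load_aso_table",
    "load_primer_table",
    "delta_ct",
    "delta_ct_per_replicate",
    "ddct_enrichment",
    "ddct_enrichment_per_replicate",
    "neurite_soma_ratio",
    "validate_oligos",
    "OligoValidation",
]

CT_COLUMNS = ["gene", "fraction", "replicate", "ct"]
COUNT_COLUMNS = ["gene", "compartment", "replicate", "count"]

_WS = re.compile(r"[\s​‌⁠﻿]")


def _clean_seq(seq: str) -> str:
    """Strip whitespace and zero-width typographic separators."""
    return _WS.sub("", str(seq)).upper()


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("ncfish.data").joinpath(name).open() as f:
        df = pd.read_csv(f)
    df["sequence"] = df["sequence"].map(_clean_seq)
    return df


def load_probe_table() -> pd.DataFrame:
    """smiFISH probe sets (columns: name, set, sequence, role)."""
    return _load_fixture("smifish_probes.csv")


def load_aso_table() -> pd.DataFrame:
    """Antisense oligos against the tRNA-Gly anticodon loop, plus scramble."""
    return _load_fixture("aso_oligos.csv")


def load_primer_table() -> pd.DataFrame:
    """qPCR primers (columns: name, lab_number, sequence)."""
    return _load_fixture("primers.csv")


def _check_ct(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns {missing}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("Ct values must be finite")
    return table


def _gene_fraction(table: pd.DataFrame, gene: str, fraction: str) -> pd.DataFrame:
    sel = table[(table["gene"] == gene) & (table["fraction"] == fraction)]
    if sel.empty:
        raise ValueError(f"no Ct rows for gene {gene!r} in fraction {fraction!r}")
    return sel


def delta_ct_per_replicate(table: pd.DataFrame, gene: str,
                           comp_a: str, comp_b: str) -> pd.Series:
    """Per-replicate Ct(comp_a) - Ct(comp_b) for one gene.

    Replicates are paired by id when both compartments carry the same
    replicate ids; otherwise the difference of compartment means is
    returned as a single unpaired value. The policy used is recorded in
    the Series name (``"paired"`` / ``"unpaired"``).
    """
    table = _check_ct(table)
    a = _gene_fraction(table, gene, comp_a)
    b = _gene_fraction(table, gene, comp_b)
    a_m = a.groupby("replicate")["ct"].mean()
    b_m = b.groupby("replicate")["ct"].mean()
    if set(a_m.index) == set(b_m.index):
        out = (a_m - b_m).sort_index()
        out.name = "paired"
        return out
    log.info("delta_ct %s: replicate ids differ between %s and %s; using means",
             gene, comp_a, comp_b)
    return pd.Series([a["ct"].mean() - b["ct"].mean()], name="unpaired")


def delta_ct(table: pd.DataFrame, gene: str, comp_a: str, comp_b: str) -> float:
    """Mean Ct(comp_a) - mean Ct(comp_b) for one gene.

    Antisymmetric in its compartments and invariant to adding a constant
    to every Ct value.
    """
    return float(delta_ct_per_replicate(table, gene, comp_a, comp_b).mean())


def ddct_enrichment_per_replicate(table: pd.DataFrame, target: str,
                                  reference: str = "Actb",
                                  comp_a: str = "mito",
                                  comp_b: str = "cyto") -> pd.Series:
    """Per-replicate 2^-ddCt of a target gene normalized to a reference.

    ddCt = dCt(target) - dCt(reference) with dCt = Ct(comp_a) - Ct(comp_b).
    When replicate ids align across genes and compartments each biological
    replicate yields one enrichment value (each dot in the figures is one
    replicate); otherwise a single pooled value is returned.
    """
    d_t = delta_ct_per_replicate(table, target, comp_a, comp_b)
    d_r = delta_ct_per_replicate(table, reference, comp_a, comp_b)
    if (d_t.name == d_r.name == "paired") and set(d_t.index) == set(d_r.index):
        ddct = (d_t - d_r).sort_index()
    else:
        ddct = pd.Series([d_t.mean() - d_r.mean()], name="pooled")
    return np.power(2.0, -ddct)


def ddct_enrichment(table: pd.DataFrame, target: str, reference: str = "Actb",
                    comp_a: str = "mito", comp_b: str = "cyto") -> float:
    """Summary 2^-ddCt enrichment: the geometric mean over replicates.

    Averaging ddCt before exponentiating (equivalently, the geometric mean
    of per-replicate enrichments) is the natural summary for fold changes:
    it makes ``ddct_enrichment(t, t)`` exactly 1 and swapping target and
    reference gives exactly the reciprocal. Figure-style arithmetic
    mean +/- SEM summaries can be computed from
    :func:`ddct_enrichment_per_replicate`.
    """
    per_rep = ddct_enrichment_per_replicate(table, target, reference,
                                            comp_a, comp_b)
    return float(np.power(2.0, np.log2(per_rep).mean()))


def neurite_soma_ratio(table: pd.DataFrame, gene: str) -> pd.Series:
    """Per-replicate neurite/soma normalized-count ratio for one gene.

    Zero soma counts yield NaN for that replicate, with a logged flag.
    """
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table is missing columns {missing}")
    sel = table[table["gene"] == gene]
    if sel.empty:
        raise ValueError(f"gene {gene!r} absent from count table")
    piv = sel.pivot_table(index="replicate", columns="compartment",
                          values="count", aggfunc="mean")
    for comp in ("neurite", "soma"):
        if comp not in piv.columns:
            raise ValueError(f"compartment {comp!r} absent for gene {gene!r}")
    soma = piv["soma"]
    if (soma == 0).any():
        log.warning("neurite_soma_ratio %s: zero soma count in some replicate", gene)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = piv["neurite"] / soma.replace(0, np.nan)
    ratio.name = gene
    return ratio


@dataclass
class OligoValidation:
    """Validation report for an oligo table."""

    n_oligos: int
    set_counts: Dict[str, int]
    set_lengths: Dict[str, List[int]]
    duplicates: List[str] = field(default_factory=list)
    alphabet_violations: List[str] = field(default_factory=list)
    expected_length: Optional[int] = None

    @property
    def passed(self) -> bool:
        if self.duplicates or self.alphabet_violations:
            return False
        if self.expected_length is not None:
            return all(set(v) == {self.expected_length}
                       for v in self.set_lengths.values())
        return True


def validate_oligos(table: pd.DataFrame,
                    expected_length: Optional[int] = None,
                    sets: Optional[List[str]] = None) -> OligoValidation:
    """Check an oligo table for set sizes, lengths, duplicates, alphabet.

    Malformed sequence characters are reported, not fatal. When
    ``expected_length`` is given, the report passes only if every set's
    oligos all have exactly that length. ``sets`` restricts the check to
    the named probe sets.
    """
    if "name" not in table.columns or "sequence" not in table.columns:
        raise ValueError("oligo table needs 'name' and 'sequence' columns")
    df = table.copy()
    df["sequence"] = df["sequence"].map(_clean_seq)
    if sets is not None and "set" in df.columns:
        df = df[df["set"].isin(sets)]
    if df["name"].duplicated().any():
        raise ValueError("oligo names must be unique")
    set_col = df["set"] if "set" in df.columns else df["name"]
    set_counts = set_col.value_counts().to_dict()
    set_lengths = {s: sorted(df.loc[set_col == s, "sequence"].str.len().unique().tolist())
                   for s in set_counts}
    dup = df.loc[df["sequence"].duplicated(keep=False), "name"].tolist()
    bad = [n for n, s in zip(df["name"], df["sequence"])
           if not s or re.search(r"[^ACGT]", s)]
    return OligoValidation(n_oligos=len(df), set_counts=set_counts,
                           set_lengths=set_lengths, duplicates=dup,
                           alphabet_violations=bad,
                           expected_length=expected_length)
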