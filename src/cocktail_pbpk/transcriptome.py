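"""Cross-species differential-expression conventions.

Implements the expression-analysis rules used alongside the PK models:
species-specific differential-expression (DE) flagging, collapsing of
human gene symbols onto mouse orthologs, per-gene-family log-fold-change
correlation, and derivation of transporter scaling multipliers for the
cirrhosis scenario from a mouse DE table.

DE computation itself (read counts to logFC/FDR) is upstream of this
package; the module consumes result tables with columns
``gene_symbol, log2fc, fdr``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MetricError
from .scenarios import ConfigError, ScalingMap

#: inclusive DE thresholds per species: (|log2fc| >=, fdr <=)
DE_THRESHOLDS = {
    "mouse": (1.0, 0.05),
    "human": (math.log2(1.5), 0.2),
}

DE_COLUMNS = ["gene_symbol", "log2fc", "fdr"]


@dataclass
class DETable:
    """Gene-level differential-expression results for one species."""

    frame: pd.DataFrame
    species: str

    def __post_init__(self):
        missing = set(DE_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ConfigError(f"DE table missing columns {sorted(missing)}")
        f = self.frame
        if f["gene_symbol"].isna().any() or (f["gene_symbol"] == "").any():
            raise ConfigError("gene_symbol must be non-empty")
        if f["gene_symbol"].duplicated().any():
            dupes = sorted(f.loc[f["gene_symbol"].duplicated(), "gene_symbol"])
            raise ConfigError(f"duplicate gene symbols: {dupes}")
        if ((f["fdr"] < 0) | (f["fdr"] > 1)).any():
            raise ConfigError("fdr must lie in [0, 1]")
        self.frame = f.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path, species: str) -> "DETable":
        return cls(pd.read_csv(path, sep="\t"), species=species)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class OrthologMap:
    """Human HGNC symbol -> mouse MGI symbol mapping (many-to-one allowed)."""

    pairs: dict[str, str]

    def __post_init__(self):
        if any(not h or not m for h, m in self.pairs.items()):
            raise ConfigError("ortholog symbols must be non-empty")

    @classmethod
    def read_tsv(cls, path) -> "OrthologMap":
        f = pd.read_csv(path, sep="\t")
        if f["human_symbol"].duplicated().any():
            raise ConfigError("a human symbol maps to more than one mouse symbol")
        return cls(dict(zip(f["human_symbol"], f["mouse_symbol"])))


def flag_de(table: DETable) -> pd.DataFrame:
    """Add a boolean ``de`` column using the species' inclusive thresholds.

    Mouse: |log2FC| >= 1 and FDR <= 0.05.  Human (relaxed):
    |log2FC| >= log2(1.5) and FDR <= 0.2.  Idempotent.
    """
    if table.species not in DE_THRESHOLDS:
        raise ConfigError(f"unknown species {table.species!r}; valid: {sorted(DE_THRESHOLDS)}")
    lfc_min, fdr_max = DE_THRESHOLDS[table.species]
    out = table.frame.copy()
    out["de"] = (out["log2fc"].abs() >= lfc_min) & (out["fdr"] <= fdr_max)
    return out


def collapse_orthologs(human: DETable, ortho: OrthologMap) -> tuple[DETable, int]:
    """Re-key a human DE table to mouse symbols.

    Many-to-one groups take the arithmetic mean of log2FC; the FDR of a
    collapsed group is the minimum of its members (a package convention
    — the most significant member represents the group).  Rows without a
    mapping are dropped; the count of dropped rows is returned.
    """
    if not ortho.pairs:
        raise ConfigError("empty ortholog map")
    f = human.frame.copy()
    f["mouse_symbol"] = f["gene_symbol"].map(ortho.pairs)
    dropped = int(f["mouse_symbol"].isna().sum())
    f = f.dropna(subset=["mouse_symbol"])
    grouped = (
        f.groupby("mouse_symbol", sort=True)
        .agg(log2fc=("log2fc", "mean"), fdr=("fdr", "min"))
        .reset_index()
        .rename(columns={"mouse_symbol": "gene_symbol"})
    )
    return DETable(grouped, species="human"), dropped


def correlate_logfc(
    mouse: DETable, human_collapsed: DETable, gene_set=None
) -> tuple[float, int, float]:
    """Pearson correlation of paired mouse/human log2 fold changes.

    Pairs are the genes shared by both tables, optionally intersected
    with ``gene_set`` (e.g. one enzyme family).  Returns ``(r, n, p)``
    with the two-sided p-value from the t transform; requires n >= 3.
    """
    m = mouse.frame.set_index("gene_symbol")["log2fc"]
    h = human_collapsed.frame.set_index("gene_symbol")["log2fc"]
    shared = m.index.intersection(h.index)
    if gene_set is not None:
        shared = shared.intersection(pd.Index(gene_set))
    if len(shared) < 3:
        raise MetricError(f"need >= 3 shared genes, got {len(shared)}")
    shared = shared.sort_values()
    res = stats.pearsonr(m.loc[shared].to_numpy(), h.loc[shared].to_numpy())
    return float(res.statistic), int(len(shared)), float(res.pvalue)


def derive_scaling_map(mouse: DETable, genes: list[str]) -> ScalingMap:
    """Transporter multipliers from a mouse DE table.

    Each requested gene gets 2**log2FC if it passes the mouse DE
    threshold and 1.0 otherwise (non-significant changes are not
    propagated into the disease model); genes absent from the table get
    1.0 with a warning.
    """
    if not genes:
        raise ConfigError("gene list must be non-empty")
    flagged = flag_de(mouse).set_index("gene_symbol")
    out = ScalingMap()
    for gene in genes:
        if gene not in flagged.index:
            warnings.warn(f"gene {gene!r} absent from DE table; multiplier 1.0")
            out.set_fixed(gene, 1.0)
        elif bool(flagged.loc[gene, "de"]):
            out.set_from_log2fc(gene, float(flagged.loc[gene, "log2fc"]))
        else:
            out.set_fixed(gene, 1.0)
    return out


def load_printed_mouse_de() -> DETable:
    """The small mouse DE table of ADME genes shipped with the package.

    Values are the study-level fold changes and adjusted p-values of the
    key metabolic and transport genes (12-month cirrhosis vs control
    mouse liver), stored as plain data for scenario construction and
    worked examples.
    """
    path = resources.files("cocktail_pbpk").joinpath("data/mouse_de_adme.tsv")
    with resources.as_file(path) as p:
        return DETable.read_tsv(p, species="mouse")
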