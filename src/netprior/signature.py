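"""Disease expression signatures: differential expression, DEG calling,
and mapping fold changes onto the interaction network.

A signature is the per-gene table of log2 fold change (case minus control),
raw p-value, Benjamini–Hochberg FDR, and the DEG call. The DEG rule is the
classic one: linear fold change above 1.5 in either direction and FDR below
0.05, both strict. DEG-mapped nodes seed every prioritizer downstream; the
pipeline refuses to run with an empty seed set because at least one
differentially expressed gene is required as input to the network methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import InteractionNetwork

__all__ = [
    "ExpressionMatrix",
    "NodeSignal",
    "differential_expression",
    "call_degs",
    "map_signature_to_network",
    "read_expression",
    "read_signature",
    "write_signature",
]

logger = logging.getLogger(__name__)

FC_THRESHOLD = 1.5
FDR_THRESHOLD = 0.05


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2 intensities plus case/control groups."""

    values: pd.DataFrame          # genes x samples, log2 scale
    groups: pd.Series             # sample -> "case" | "control"

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        case = [s for s in self.samples if self.groups[s] == "case"]
        control = [s for s in self.samples if self.groups[s] == "control"]
        return self.values[case], self.values[control]


@dataclass
class NodeSignal:
    """Fold-change weights mapped onto the network.

    ``weights[i]`` is 0 for every node outside ``deg_nodes``; inside it is
    the (absolute, by default) log2 fold change of the mapped DEG.
    """

    weights: np.ndarray           # aligned with network node order
    deg_nodes: set = field(default_factory=set)
    nodes: list = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.weights))


def differential_expression(expr: ExpressionMatrix,
                            fc_threshold: float = FC_THRESHOLD,
                            fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test on log2 values with BH correction.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean case
    minus mean control), ``pvalue``, ``fdr`` and ``is_deg``. Genes constant
    across all samples get p-value 1 by convention.
    """
    case, control = expr.split()
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError(
            f"need >=2 samples per group, got case={case.shape[1]}, "
            f"control={control.shape[1]}")
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(case.to_numpy(), control.to_numpy(),
                                   axis=1, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    # constant genes (zero variance in both groups) yield nan; convention p=1
    pvals[~np.isfinite(pvals)] = 1.0
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    sig = pd.DataFrame({
        "log2fc": log2fc.to_numpy(dtype=float),
        "pvalue": pvals,
        "fdr": fdr,
    }, index=expr.values.index)
    sig["is_deg"] = _deg_mask(sig, fc_threshold, fdr_threshold)
    return sig


def _deg_mask(sig: pd.DataFrame, fc_threshold: float,
              fdr_threshold: float) -> pd.Series:
    linear_fc = np.exp2(sig["log2fc"].abs())
    return (linear_fc > fc_threshold) & (sig["fdr"] < fdr_threshold)


def call_degs(sig: pd.DataFrame, fc_threshold: float = FC_THRESHOLD,
              fdr_threshold: float = FDR_THRESHOLD) -> set:
    """Genes with linear |fold change| > ``fc_threshold`` AND
    fdr < ``fdr_threshold`` (both strict; boundary values excluded).

    The fold-change test is two-sided on the linear scale: a gene passes if
    its linear FC exceeds the threshold or falls below its reciprocal.
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    mask = _deg_mask(sig, fc_threshold, fdr_threshold)
    return set(sig.index[mask])


def map_signature_to_network(sig: pd.DataFrame, net: InteractionNetwork,
                             id_map: Optional[Mapping[str, str]] = None,
                             signed: bool = False,
                             fc_threshold: float = FC_THRESHOLD,
                             fdr_threshold: float = FDR_THRESHOLD) -> NodeSignal:
    """Map DEG fold changes onto network nodes.

    Non-DEG nodes get weight 0. By default the weight is |log2fc| so that
    down-regulated seeds carry positive mass (the prioritizers need
    non-negative input); ``signed=True`` keeps the sign. Many-to-one gene
    to node mappings are allowed (complex/family nodes); on collision the
    maximum weight wins. Genes absent from the network are dropped with a
    logged count.

    Raises ``ValueError`` if no DEG maps into the network: at least one
    differentially expressed gene is required as input to the network
    methods.
    """
    id_map = dict(id_map) if id_map is not None else {}
    degs = call_degs(sig, fc_threshold, fdr_threshold)
    idx = net.index()
    weights = np.zeros(net.n_nodes)
    deg_nodes: set = set()
    n_dropped = 0
    for gene in sig.index:
        node = id_map.get(gene, gene)
        if node not in idx:
            n_dropped += 1
            continue
        if gene in degs:
            lfc = float(sig.loc[gene, "log2fc"])
            w = lfc if signed else abs(lfc)
            i = idx[node]
            if abs(w) >= abs(weights[i]):
                weights[i] = w
            deg_nodes.add(node)
    if n_dropped:
        logger.info("dropped %d signature genes absent from the network",
                    n_dropped)
    if not deg_nodes:
        raise ValueError(
            "no differentially expressed gene maps into the network; "
            "at least one DEG is required as input")
    return NodeSignal(weights=weights, deg_nodes=deg_nodes, nodes=net.nodes)


# -- file I/O ----------------------------------------------------------

def read_expression(matrix_path: str | Path,
                    groups_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene id, header sample ids)
    and a two-column ``sample<TAB>group`` TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0,
                         header=None, names=["sample", "group"])["group"]
    return ExpressionMatrix(values=values, groups=groups)


def read_signature(path: str | Path) -> pd.DataFrame:
    """Read a precomputed signature TSV: gene, log2fc, pvalue, fdr."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    required = {"log2fc", "pvalue", "fdr"}
    missing = required - set(sig.columns)
    if missing:
        raise ValueError(f"signature file missing columns: {sorted(missing)}")
    if "is_deg" not in sig.columns:
        sig["is_deg"] = _deg_mask(sig, FC_THRESHOLD, FDR_THRESHOLD)
    return sig


def write_signature(sig: pd.DataFrame, path: str | Path) -> None:
    sig.to_csv(path, sep="\t", index_label="gene")
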