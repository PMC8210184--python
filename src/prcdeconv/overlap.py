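"""Overlap and enrichment statistics.

Hypergeometric over-representation of a query set in a reference set within
a stated universe; the two-sided Fisher exact test for 2x2 count tables;
Benjamini-Hochberg FDR adjustment; and the differential-exon-usage (DEU)
overlap analysis, which thresholds a per-exon p-value table at a BH-adjusted
cutoff, deduplicates to genes and tests the resulting gene set against
reference gene collections.

Overlap p-values are upper-tail and include the observed count,
p = P(X >= k), the standard over-representation convention.  The Fisher
test uses the minimum-likelihood rule (sum over same-margin tables whose
point probability does not exceed the observed one), computed by exact
integer enumeration so ties are resolved without floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError


@dataclass(frozen=True)
class OverlapTestResult:
    """Hypergeometric overlap of a query set with a reference set.

    k = |query ∩ reference|, K = |reference|, n = |query|, N = |universe|;
    p_value = P(X >= k) for X ~ Hypergeometric(N, K, n).
    """

    k: int
    K: int
    n: int
    N: int
    p_value: float
    name: str = ""


def hypergeom_overlap(query, reference, universe) -> OverlapTestResult:
    """Upper-tail hypergeometric test of query/reference overlap.

    Both sets must lie inside the universe.  scipy's survival function is
    used, which works in log-space and is stable for universes far beyond
    1e3 genes.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = frozenset(query)
    reference = frozenset(reference)
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    if not reference <= universe:
        raise ValueError("reference is not a subset of the universe")
    k = len(query & reference)
    K, n, N = len(reference), len(query), len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTestResult(k=k, K=K, n=n, N=N, p_value=min(1.0, max(p, 0.0)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Sums the exact probabilities of all tables with the observed margins
    whose point probability is <= the observed table's, comparing exact
    integer weights so near-ties need no tolerance.  A zero margin leaves a
    single admissible table and p = 1.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    total = a + b + c + d
    if total == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    weights = [comb(r1, k) * comb(total - r1, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return num / comb(total, c1)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH-adjusted p-values, order-preserving, all in [p, 1]."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_deu_table(path) -> pd.DataFrame:
    """Read a DEU results table (gene_id, exon_id, p_value), validating it."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene_id", "exon_id", "p_value") if c not in df.columns]
    if missing:
        raise SchemaError(f"DEU table missing columns {missing}")
    return validate_deu_table(df)


def validate_deu_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["gene_id"] = df["gene_id"].astype(str)
    df["exon_id"] = df["exon_id"].astype(str)
    df["p_value"] = df["p_value"].astype(float)
    if df.empty:
        raise SchemaError("DEU table is empty")
    if df.duplicated(subset=["gene_id", "exon_id"]).any():
        dup = df[df.duplicated(subset=["gene_id", "exon_id"])].iloc[0]
        raise SchemaError(
            f"duplicated (gene, exon) pair ({dup.gene_id!r}, {dup.exon_id!r})"
        )
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise SchemaError("DEU raw p-values must lie in [0, 1]")
    return df


def significant_deu_genes(deu: pd.DataFrame, alpha: float = 0.05) -> frozenset:
    """Genes with at least one exon at BH-adjusted p < alpha (counted once)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    deu = validate_deu_table(deu)
    adj = benjamini_hochberg(deu["p_value"].to_numpy())
    return frozenset(deu.loc[adj < alpha, "gene_id"])


def deu_overlap_analysis(
    deu: pd.DataFrame,
    reference: dict,
    alpha: float = 0.05,
    universe=None,
):
    """Test the DEU gene set against each reference gene collection.

    The DEU gene set is formed at the BH-adjusted per-exon threshold and
    deduplicated to genes.  The universe defaults to all genes present in
    the DEU table (every gene that could have been called) and is reported
    in each result; reference sets are clipped to the universe.

    Returns (results table, DEU gene set).
    """
    deu = validate_deu_table(deu)
    sig = significant_deu_genes(deu, alpha)
    if universe is None:
        universe = frozenset(deu["gene_id"])
    universe = frozenset(universe)
    rows = []
    for name, ref in reference.items():
        res = hypergeom_overlap(sig, frozenset(ref) & universe, universe)
        rows.append(
            {
                "set": name,
                "k": res.k,
                "K": res.K,
                "n": res.n,
                "N": res.N,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("set"), sig


def ora_collections(query, collections: dict, universe) -> pd.DataFrame:
    """Over-representation of a query set in each collection, BH across collections.

    A generic replacement for network-enrichment engines: each user-supplied
    collection is tested by the upper-tail hypergeometric against the stated
    universe, and q-values are BH-adjusted across the collections tested.
    """
    universe = frozenset(universe)
    query = frozenset(query) & universe
    rows = []
    for name, ref in collections.items():
        res = hypergeom_overlap(query, frozenset(ref) & universe, universe)
        rows.append(
            {"set": name, "k": res.k, "K": res.K, "n": res.n, "N": res.N, "p": res.p_value}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = benjamini_hochberg(out["p"].to_numpy()) if len(out) else []
    return out


def read_gene_set(path) -> frozenset:
    """One gene ID per line; blank lines and '#' comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return frozenset(ids)


def read_gmt(path) -> dict:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"malformed GMT line: {line[:50]!r}")
        out[parts[0]] = frozenset(g for g in parts[2:] if g)
    return out
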