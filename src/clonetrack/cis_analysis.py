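"""Common insertion sites (CIS) and gene-by-gene genomic-track comparison.

A CIS gene is one hit by significantly more integrations than expected for
its length — a genotoxicity alarm in gene-therapy safety monitoring.  The
Grubbs-style test works on per-gene integration frequencies normalized by
gene length: frequencies are rescaled, -log2 transformed into an
approximately normal score x_g, and each gene's deviation below the mean of
x (i.e. toward *high* frequency) is converted to a one-sided outlier
t statistic with Benjamini-Hochberg FDR correction.

:func:`fisher_track_compare` compares two integration profiles gene by gene
with two-sided Fisher exact tests on 2x2 tables of gene vs. non-gene IS
counts (e.g. two patients, or two vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data_model import event_columns


@dataclass
class GeneRecord:
    gene_name: str
    gene_length_bp: int
    is_count: int
    raw_freq: float
    z: float
    t: float
    p_value: float
    fdr: float
    significant: bool


def grubbs_t_from_z(z: float, n: int) -> float:
    """Convert a standardized deviate to the Grubbs outlier t statistic.

    t = z * sqrt(n - 2) / sqrt(n - 1 - z^2); +inf when z^2 >= n - 1
    (the deviate is at the sample extreme permitted by n).
    """
    denom = n - 1 - z * z
    if denom <= 0:
        return float("inf")
    return float(z * np.sqrt(n - 2) / np.sqrt(denom))


def cis_grubbs(
    m: pd.DataFrame,
    gene_lengths: pd.DataFrame,
    alpha: float = 0.05,
    scale: str = "mean_length",
    strand_aware: bool = True,
    classical_correction: bool = False,
) -> pd.DataFrame:
    """Per-gene Grubbs outlier test for over-targeting.

    For each annotated gene g with L_g the length in bp and k_g the number
    of distinct IS falling in it:

    * raw_freq_g = k_g / L_g
    * scaled_g = raw_freq_g * mean(L)  (dimensionless rescaling; any positive
      constant cancels in the z standardization and cannot change calls)
    * x_g = -log2(scaled_g); z_g = (mean(x) - x_g) / sd(x)  (large z means
      over-targeted); t_g per :func:`grubbs_t_from_z`; p_g = upper tail of
      Student t with n - 2 df; FDR by Benjamini-Hochberg.

    ``classical_correction`` multiplies each p by n (Bonferroni-style
    classical Grubbs) before FDR.  Requires >= 3 genes; zero spread in x
    yields no significant genes with missing p-values.

    ``gene_lengths``: DataFrame with columns gene_name, length_bp.
    """
    if not {"gene_name", "length_bp"}.issubset(gene_lengths.columns):
        raise ValueError("gene_lengths needs columns gene_name, length_bp")
    ev_cols = event_columns(strand_aware)
    annotated = m[m["GeneName"].notna()].drop_duplicates(ev_cols + ["GeneName"])
    counts = annotated.groupby("GeneName").size().rename("is_count")
    tab = gene_lengths.set_index("gene_name").join(counts, how="inner")
    tab = tab[tab["is_count"] > 0]
    n = len(tab)
    if n < 3:
        raise ValueError(f"need >= 3 genes with integrations, got {n}")
    missing = set(annotated["GeneName"].unique()) - set(gene_lengths["gene_name"])
    if missing:
        raise ValueError(f"genes without a length annotation: {sorted(missing)[:10]}")

    length = tab["length_bp"].to_numpy(dtype=float)
    k = tab["is_count"].to_numpy(dtype=float)
    raw = k / length
    scaled = raw * (length.mean() if scale == "mean_length" else 1.0)
    x = -np.log2(scaled)
    sd = x.std(ddof=1)
    if sd == 0:
        z = np.full(n, np.nan)
        p = np.full(n, np.nan)
        t = np.full(n, np.nan)
        fdr = np.full(n, np.nan)
        sig = np.zeros(n, dtype=bool)
    else:
        z = (x.mean() - x) / sd
        t = np.array([grubbs_t_from_z(zi, n) for zi in z])
        p = sps.t.sf(t, df=n - 2)
        if classical_correction:
            p = np.minimum(p * n, 1.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        sig = fdr < alpha
    out = pd.DataFrame(
        {
            "gene_name": tab.index,
            "gene_length_bp": tab["length_bp"].to_numpy(),
            "is_count": tab["is_count"].to_numpy(),
            "raw_freq": raw,
            "z": z,
            "t": t,
            "p_value": p,
            "fdr": fdr,
            "significant": sig,
        }
    ).reset_index(drop=True)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def gene_frequency(
    m: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    key: list[str] | None = None,
    strand_aware: bool = True,
    id_col: str = "CompleteAmplificationID",
) -> pd.DataFrame:
    """Per-group, per-gene distinct-IS counts and relative gene frequencies.

    frequency = distinct IS in gene / total distinct IS in the group
    (intergenic IS count toward the denominator, so frequencies sum to <= 1).
    """
    ev_cols = event_columns(strand_aware)
    if key:
        if meta is None:
            raise ValueError("metadata required when a key is given")
        j = m.merge(meta[[id_col] + list(key)], on=id_col, how="left")
        group_cols = list(key)
    else:
        j = m.assign(_all="all")
        group_cols = ["_all"]
    rows = []
    for kt, grp in j.groupby(group_cols, dropna=False):
        kt = kt if isinstance(kt, tuple) else (kt,)
        uniq = grp.drop_duplicates(ev_cols)
        total = len(uniq)
        per_gene = uniq[uniq["GeneName"].notna()].groupby("GeneName").size()
        for gene, cnt in per_gene.items():
            rows.append(
                dict(zip(group_cols, kt))
                | {"gene_name": gene, "is_count": int(cnt), "frequency": cnt / total}
            )
    out = pd.DataFrame(rows)
    if "_all" in out.columns:
        out = out.drop(columns="_all")
    return out


def fisher_track_compare(
    a: pd.DataFrame,
    b: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Gene-by-gene Fisher exact comparison of two integration profiles.

    ``a`` and ``b``: per-gene count tables (columns gene_name, is_count), as
    produced by :func:`gene_frequency` for a single group.  For each gene of
    either track, the 2x2 table [[k_A, N_A - k_A], [k_B, N_B - k_B]] is
    tested two-sided; ``adjust`` in {"none", "BH"}.
    """
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    ca = a.set_index("gene_name")["is_count"]
    cb = b.set_index("gene_name")["is_count"]
    na, nb = int(ca.sum()), int(cb.sum())
    if na == 0 or nb == 0:
        raise ValueError("both tracks need a positive total IS count")
    genes = sorted(set(ca.index) | set(cb.index))
    rows = []
    for g in genes:
        ka = int(ca.get(g, 0))
        kb = int(cb.get(g, 0))
        odds, p = sps.fisher_exact([[ka, na - ka], [kb, nb - kb]], alternative="two-sided")
        rows.append(
            {
                "gene_name": g,
                "count_a": ka,
                "count_b": kb,
                "freq_a": ka / na,
                "freq_b": kb / nb,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    padj = (
        multipletests(out["p_value"], method="fdr_bh")[1]
        if adjust == "BH"
        else out["p_value"].to_numpy()
    )
    out["p_adjusted"] = padj
    out["significant"] = out["p_adjusted"] < alpha
    return out


def circos_density(
    m: pd.DataFrame, window_bp: int = 1_000_000, strand_aware: bool = True
) -> pd.DataFrame:
    """Per-chromosome distinct-IS counts in fixed windows (circos data layer)."""
    ev_cols = event_columns(strand_aware)
    uniq = m.drop_duplicates(ev_cols)
    dens = (
        uniq.assign(window_start=(uniq["integration_locus"] // window_bp) * window_bp)
        .groupby(["chr", "window_start"])
        .size()
        .rename("is_count")
        .reset_index()
    )
    return dens.sort_values(["chr", "window_start"]).reset_index(drop=True)
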