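"""Differential-expression screening between tumor and normal B-cell stages.

The screen mirrors a classical microarray workflow: per-stage two-sample
t-tests of tumor versus each normal differentiation stage, a |log2 FC| > 1
fold-change filter (values are log2, so FC > 2 ⇔ difference > 1), BH FDR
control per contrast, and a Venn-style intersection that nominates genes
significant against *every* stage.  A one-way ANOVA across all groups (with
Bonferroni over the nominated family) backs the intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError

__all__ = [
    "log2_fold_change",
    "two_group_test",
    "bh_adjust",
    "bonferroni_adjust",
    "anova_one_way",
    "screen_candidates",
    "StageContrastSet",
]


def _group_values(mat: pd.DataFrame, samples) -> np.ndarray:
    samples = list(samples)
    if not samples:
        raise DomainError("empty sample group")
    missing = [s for s in samples if s not in mat.columns]
    if missing:
        raise DomainError(f"samples absent from matrix: {missing}")
    return mat[samples].to_numpy(float)


def log2_fold_change(mat: pd.DataFrame, samples_a, samples_b) -> pd.Series:
    """mean(A) − mean(B) per gene, in log2 units (FC > 2 ⇔ value > 1)."""
    a = _group_values(mat, samples_a)
    b = _group_values(mat, samples_b)
    if set(samples_a) & set(samples_b):
        raise DomainError("sample groups overlap")
    return pd.Series(a.mean(axis=1) - b.mean(axis=1), index=mat.index, name="log2_fc")


def two_group_test(
    mat: pd.DataFrame, samples_a, samples_b, flavor: str = "student"
) -> pd.DataFrame:
    """Two-sided two-sample t-test per gene.

    ``student`` pools variances (df = nA+nB−2); ``welch`` uses the
    Welch–Satterthwaite approximation.  Genes with zero variance in both
    groups get t = 0, p = 1 when means agree (never NaN) and p = 0 otherwise.
    """
    a = _group_values(mat, samples_a)
    b = _group_values(mat, samples_b)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise DomainError("need at least 2 samples per group for a t-test")
    dm = a.mean(axis=1) - b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    if flavor == "student":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = np.full_like(dm, na + nb - 2.0)
    elif flavor == "welch":
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
    else:
        raise DomainError(f"unknown t-test flavor {flavor!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dm / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = se == 0
    t = np.where(zero, np.where(dm == 0, 0.0, np.sign(dm) * np.inf), t)
    p = np.where(zero, np.where(dm == 0, 1.0, 0.0), p)
    return pd.DataFrame({"t": t, "p": p}, index=mat.index)


def _check_probabilities(p: np.ndarray) -> None:
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise DomainError("p-values must lie in [0, 1]")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, float)
    _check_probabilities(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni: p × m clipped to 1; m defaults to len(p)."""
    p = np.asarray(p_values, float)
    _check_probabilities(p)
    m = p.size if m is None else m
    return np.minimum(p * m, 1.0)


def anova_one_way(mat: pd.DataFrame, group_map: dict) -> pd.DataFrame:
    """Per-gene one-way ANOVA F-test across the groups of ``group_map``.

    Bonferroni multiplies each raw p by the number of genes tested in this
    call (the nominated family).  All-identical genes get F = 0, p = 1.
    """
    groups: dict[str, list] = {}
    for sample, grp in group_map.items():
        groups.setdefault(grp, []).append(sample)
    if len(groups) < 2:
        raise DomainError("ANOVA needs at least two groups")
    arrays = []
    for grp, samples in groups.items():
        if len(samples) < 2:
            raise DomainError(f"group {grp!r} has fewer than 2 samples")
        arrays.append(_group_values(mat, samples))
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(*arrays, axis=1)
    # degenerate genes: no variance at all -> no evidence (F=0, p=1);
    # between-group variance with zero within-variance -> p=0
    total = np.concatenate(arrays, axis=1)
    flat = total.var(axis=1) == 0
    f = np.where(flat, 0.0, f)
    p = np.where(flat, 1.0, p)
    within = sum(((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for arr in arrays)
    degenerate = (~flat) & (within == 0)
    f = np.where(degenerate, np.inf, f)
    p = np.where(degenerate, 0.0, p)
    return pd.DataFrame(
        {"F": f, "p": p, "p_bonferroni": bonferroni_adjust(p)}, index=mat.index
    )


@dataclass
class StageContrastSet:
    """Tumor-vs-stage contrasts plus the Venn intersection of significant genes."""

    contrasts: dict[str, pd.DataFrame]
    candidates: pd.DataFrame  # gene_id, direction, anova_p, anova_p_bonferroni
    tumor_group: str
    fc_threshold: float
    p_threshold: float
    use_adjusted_p: bool = True
    stages: list[str] = field(default_factory=list)

    @property
    def intersection(self) -> list[str]:
        return list(self.candidates.index)

    def candidate_lncrnas(self, catalog) -> list[str]:
        return [g for g in self.intersection if catalog.biotype_of(g) == "lncRNA"]


def screen_candidates(
    mat: pd.DataFrame,
    sheet: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    tumor_group: str = "DLBCL",
    use_adjusted_p: bool = True,
    flavor: str = "student",
) -> StageContrastSet:
    """Run the full screen: per-stage contrasts, intersection, ANOVA.

    Significance per contrast: |log2 FC| > log2(fc_threshold) AND
    (BH-adjusted by default, raw with ``use_adjusted_p=False``) p < p_threshold,
    both strict.  Candidates = genes significant in every tumor-vs-stage
    contrast, reported with their direction in tumor (up/down/mixed); the
    ANOVA Bonferroni family is the candidate set itself.
    """
    groups = sheet.groupby("group")["sample_id"].apply(list).to_dict()
    if tumor_group not in groups:
        raise DomainError(f"tumor group {tumor_group!r} absent from sample sheet")
    stages = sorted(g for g in groups if g != tumor_group)
    if not stages:
        raise DomainError("no normal stage groups in sample sheet")
    tumor_samples = groups[tumor_group]
    lfc_cut = np.log2(fc_threshold)

    contrasts: dict[str, pd.DataFrame] = {}
    sig_all = pd.Series(True, index=mat.index)
    signs = []
    for stage in stages:
        lfc = log2_fold_change(mat, tumor_samples, groups[stage])
        tp = two_group_test(mat, tumor_samples, groups[stage], flavor=flavor)
        q = bh_adjust(tp["p"].to_numpy())
        p_used = q if use_adjusted_p else tp["p"].to_numpy()
        sig = (np.abs(lfc.to_numpy()) > lfc_cut) & (p_used < p_threshold)
        contrasts[stage] = pd.DataFrame(
            {
                "log2_fc": lfc,
                "t": tp["t"],
                "p": tp["p"],
                "q": q,
                "significant": sig,
            },
            index=mat.index,
        )
        sig_all &= sig
        signs.append(np.sign(lfc.to_numpy()))
    members = mat.index[sig_all.to_numpy()]
    sign_mat = np.vstack(signs)[:, sig_all.to_numpy()]
    direction = np.where(
        (sign_mat > 0).all(axis=0), "up", np.where((sign_mat < 0).all(axis=0), "down", "mixed")
    )
    candidates = pd.DataFrame({"direction": direction}, index=members)
    if len(members):
        group_map = dict(zip(sheet["sample_id"], sheet["group"]))
        anova = anova_one_way(mat.loc[members], group_map)
        candidates["anova_p"] = anova["p"]
        candidates["anova_p_bonferroni"] = anova["p_bonferroni"]
    else:
        candidates["anova_p"] = pd.Series(dtype=float)
        candidates["anova_p_bonferroni"] = pd.Series(dtype=float)
    return StageContrastSet(
        contrasts=contrasts,
        candidates=candidates,
        tumor_group=tumor_group,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        use_adjusted_p=use_adjusted_p,
        stages=stages,
    )


def write_screen_results(result: StageContrastSet, contrast_path, intersection_path) -> None:
    """TSV export: one row per gene per contrast, plus a plain candidate list."""
    frames = []
    for stage, tab in result.contrasts.items():
        frame = tab.reset_index(names="gene_id")
        frame.insert(1, "contrast", f"{result.tumor_group}_vs_{stage}")
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(contrast_path, sep="\t", index=False)
    with open(intersection_path, "w", encoding="utf-8") as fh:
        for gene in result.intersection:
            fh.write(f"{gene}\n")
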