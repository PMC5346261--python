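"""Multiple-testing correction and the four-way regulatory classification.

A CpG is called AS-genetic when its allele-pooled ASM test is
significant (q < 0.1), NAS-genetic when only the non-allelic mQTL is
(q < 0.1), epigenetic when neither genetic test is significant but the
genotype-independent imbalance test is (q < 0.01), and none otherwise.
Per-CpG q-values aggregate over a CpG's phasing/cis pairs by the
minimum q.
"""

from __future__ import annotations

from typing import Mapping, Set

import numpy as np
import pandas as pd

AS_GENETIC = "AS-genetic"
NAS_GENETIC = "NAS-genetic"
EPIGENETIC = "epigenetic"
NONE = "none"


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonisation."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    m = len(p)
    if m == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_cpg(asm_q, mqtl_q, git_q,
                 asm_thresh: float = 0.1, mqtl_thresh: float = 0.1,
                 git_thresh: float = 0.01) -> np.ndarray:
    """Vectorised four-way class from the three q-values.

    Missing q-values (NaN) are treated as non-significant.  The
    partition is exhaustive and mutually exclusive by construction.
    """
    asm_q = np.atleast_1d(np.asarray(asm_q, dtype=float))
    mqtl_q = np.atleast_1d(np.asarray(mqtl_q, dtype=float))
    git_q = np.atleast_1d(np.asarray(git_q, dtype=float))
    asm_sig = np.nan_to_num(asm_q, nan=1.0) < asm_thresh
    mqtl_sig = np.nan_to_num(mqtl_q, nan=1.0) < mqtl_thresh
    git_sig = np.nan_to_num(git_q, nan=1.0) < git_thresh
    out = np.full(asm_sig.shape, NONE, dtype=object)
    out[git_sig] = EPIGENETIC
    out[mqtl_sig] = NAS_GENETIC
    out[asm_sig] = AS_GENETIC
    return out


def classify_results(asm_res: pd.DataFrame, mqtl_res: pd.DataFrame,
                     git_res: pd.DataFrame) -> pd.DataFrame:
    """Join the three result tables into per-CpG class records.

    Each input needs columns cpg_id and q; per-CpG q is the minimum over
    that CpG's pairs.  CpGs absent from a table are untested there
    (q = NaN, treated as non-significant and flagged).
    """
    def min_q(res: pd.DataFrame, name: str) -> pd.Series:
        if len(res) == 0:
            return pd.Series(dtype=float, name=name)
        return res.groupby("cpg_id")["q"].min().rename(name)

    merged = pd.concat(
        [min_q(asm_res, "asm_q"), min_q(mqtl_res, "mqtl_q"),
         min_q(git_res, "git_q")],
        axis=1).reset_index().rename(columns={"index": "cpg_id"})
    merged["n_tests_missing"] = merged[["asm_q", "mqtl_q", "git_q"]] \
        .isna().sum(axis=1)
    merged["class"] = classify_cpg(merged["asm_q"], merged["mqtl_q"],
                                   merged["git_q"])
    return merged


def tissue_sharing(sets: Mapping[str, Set[str]],
                   universe: Set[str]) -> pd.DataFrame:
    """Partition per-tissue significant CpG sets by sharing pattern.

    ``sets`` maps tissue name -> significant CpGs; every set must be a
    subset of ``universe`` (the CpGs tested in all tissues).  Returns
    one row per tissue with counts: n_significant, specific (in that
    tissue only), all_shared (in every tissue), and shared_<other>
    (in exactly this tissue and that one other).
    """
    if len(sets) < 2:
        raise ValueError("need at least two tissue sets")
    names = list(sets)
    for name, s in sets.items():
        extra = set(s) - set(universe)
        if extra:
            raise ValueError(
                f"set {name!r} contains CpGs outside the universe: "
                f"{sorted(extra)[:5]}")
    rows = []
    for name in names:
        s = set(sets[name])
        others = [o for o in names if o != name]
        in_all = s.intersection(*(sets[o] for o in others))
        specific = s.difference(*(sets[o] for o in others))
        row = {"tissue": name, "n_significant": len(s),
               "specific": len(specific), "all_shared": len(in_all)}
        for o in others:
            exactly_pair = {
                c for c in s & set(sets[o])
                if not any(c in sets[x] for x in names if x not in (name, o))
            }
            row[f"shared_{o}"] = len(exactly_pair)
        rows.append(row)
    return pd.DataFrame(rows)
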