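"""Reader-agreement statistics: Cohen's kappa, accuracy, Wilcoxon, McNemar.

This layer scores grading tables from a two-stage reading protocol — grades
assigned on T1-w + non-fs T2-w only (``two_sequence``) versus grades assigned
after adding a synthetic T2-w fs image (``synthetic_protocol``) — against a
ground-truth grading. Agreement per pathology is unweighted Cohen's kappa
with a 95% asymptotic confidence interval; protocols are compared by a
Wilcoxon signed-rank test across the pathology-wise kappa pairs and by
McNemar's test on per-item grading correctness.

Conventions, fixed deliberately:

* kappa is unweighted (the grades are treated as categorical);
* both readers' gradings are pooled as independent rows before kappa;
* Wilcoxon discards zero differences and uses the asymptotic two-sided
  normal approximation with mid-ranks and tie correction;
* McNemar is exact (two-sided binomial) while the discordant count is below
  25, continuity-corrected chi-square otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import PATHOLOGY_KINDS

PROTOCOLS = ("two_sequence", "synthetic_protocol")


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float
    n: int
    undefined: bool = False

    def as_tuple(self) -> tuple[float, tuple[float, float]]:
        return self.kappa, (self.ci_low, self.ci_high)


def cohens_kappa(g1, g2, alpha: float = 0.05) -> KappaResult:
    """Unweighted Cohen's kappa between two grade sequences with 95% CI.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o`` and
    chance agreement ``p_e`` from the marginal distributions; the CI is
    ``kappa +/- z * SE`` with the large-sample (Fleiss-Cohen-Everitt)
    standard error. When both raters are constant and identical
    (``p_e = 1``), kappa is undefined and flagged.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("grade sequences must be equal-length 1-D")
    n = len(g1)
    if n < 2:
        raise ValueError("need at least 2 paired grades")
    cats = np.unique(np.concatenate([g1, g2]))
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for a, b in zip(g1, g2):
        table[idx[a], idx[b]] += 1
    return kappa_from_table(table, alpha=alpha)


def kappa_from_table(table: np.ndarray, alpha: float = 0.05) -> KappaResult:
    """Kappa and asymptotic CI from a square contingency table of counts."""
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("contingency table must be square")
    n = table.sum()
    if n < 2:
        raise ValueError("need at least 2 paired grades")
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = np.trace(p)
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        return KappaResult(math.nan, math.nan, math.nan, math.nan, int(n),
                           undefined=True)
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance
    k = table.shape[0]
    term1 = sum(p[i, i] * ((1 - pe) - (col[i] + row[i]) * (1 - po)) ** 2
                for i in range(k))
    term2 = (1 - po) ** 2 * sum(p[i, j] * (col[i] + row[j]) ** 2
                                for i in range(k) for j in range(k) if i != j)
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return KappaResult(float(kappa), float(kappa - z * se), float(kappa + z * se),
                       se, int(n))


def grading_accuracy(g, gt) -> float:
    """Fraction of exact grade matches."""
    g = np.asarray(g)
    gt = np.asarray(gt)
    if g.shape != gt.shape:
        raise ValueError(f"length mismatch: {g.shape} vs {gt.shape}")
    if g.size == 0:
        raise ValueError("empty grade sequences")
    return float(np.mean(g == gt))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (paired)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    z: float
    p: float
    n_nonzero: int
    w_plus: float
    undefined: bool = False


def wilcoxon_signed_rank(pairs) -> WilcoxonResult:
    """Asymptotic two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are discarded; absolute differences are mid-ranked with
    tie correction in the normal approximation; no continuity correction.
    The sign convention is ``difference = a - b`` for pairs ``(a, b)``, so
    swapping the members negates z and leaves p unchanged. All-zero
    differences are flagged undefined.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 1:
        raise ValueError("pairs must be a non-empty sequence of (a, b) tuples")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(math.nan, math.nan, 0, math.nan, undefined=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(math.nan, math.nan, n, w_plus, undefined=True)
    z = (w_plus - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(float(z), float(min(p, 1.0)), n, w_plus)


def wilcoxon_exact(pairs) -> float:
    """Exact-enumeration two-sided p for small samples; the independent
    oracle for the asymptotic approximation (enumerates all 2^n sign
    assignments, so use only for n <= ~15)."""
    arr = np.asarray(pairs, dtype=np.float64)
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences zero")
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    dev = abs(w_obs - mu)
    count = 0
    for mask in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / 2 ** n


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McNemarResult:
    p: float
    b: int
    c: int
    method: str
    degenerate: bool = False


def mcnemar_test(correct_a, correct_b, exact_threshold: int = 25) -> McNemarResult:
    """McNemar's test on paired correctness indicators.

    ``b`` counts items a got right and b wrong; ``c`` the reverse. Exact
    two-sided binomial p while ``b + c < exact_threshold``; otherwise the
    continuity-corrected chi-square. ``b + c = 0`` yields p = 1, flagged
    degenerate.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("correctness sequences must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    nd = b + c
    if nd == 0:
        return McNemarResult(1.0, b, c, "degenerate", degenerate=True)
    if nd < exact_threshold:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), nd, 0.5))
        return McNemarResult(float(p), b, c, "exact")
    chi2 = (abs(b - c) - 1) ** 2 / nd
    return McNemarResult(float(stats.chi2.sf(chi2, df=1)), b, c,
                         "chi2_corrected")


# ---------------------------------------------------------------------------
# study summary
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Per-pathology agreement under both protocols plus protocol-level tests."""

    per_pathology: dict = field(default_factory=dict)
    mean_kappa: dict = field(default_factory=dict)
    wilcoxon: WilcoxonResult | None = None
    mcnemar: dict = field(default_factory=dict)

    def kappa_table(self) -> pd.DataFrame:
        """Per-pathology kappa [CI] for both protocols."""
        rows = []
        for kind, res in self.per_pathology.items():
            row = {"pathology": kind}
            for proto in PROTOCOLS:
                kr: KappaResult = res[proto]["kappa"]
                row[f"kappa_{proto}"] = kr.kappa
                row[f"ci_{proto}"] = (kr.ci_low, kr.ci_high)
            rows.append(row)
        return pd.DataFrame(rows)

    def accuracy_table(self) -> pd.DataFrame:
        rows = []
        for kind, res in self.per_pathology.items():
            rows.append({
                "pathology": kind,
                **{f"accuracy_{proto}": res[proto]["accuracy"] for proto in PROTOCOLS},
                "mcnemar_p": self.mcnemar.get(kind).p if kind in self.mcnemar else None,
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (KappaResult, WilcoxonResult, McNemarResult)):
                return o.__dict__ | {"_type": type(o).__name__}
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(str(type(o)))
        return json.dumps({
            "per_pathology": self.per_pathology,
            "mean_kappa": self.mean_kappa,
            "wilcoxon": self.wilcoxon,
            "mcnemar": self.mcnemar,
        }, default=enc, indent=2)


def aggregate_kappa_pairs(kappa_pairs: dict[str, tuple[float, float]]) -> dict:
    """Aggregate per-pathology kappa pairs ``(two_sequence, synthetic)``.

    Returns the mean kappa per protocol (arithmetic mean over pathologies)
    and the Wilcoxon signed-rank comparison of the pairs, with the difference
    taken as synthetic minus two-sequence. Pairs with an undefined (NaN)
    kappa on either side are excluded from both aggregates.
    """
    defined = {k: v for k, v in kappa_pairs.items()
               if math.isfinite(v[0]) and math.isfinite(v[1])}
    if not defined:
        raise ValueError("no defined kappa pairs supplied")
    two = [v[0] for v in defined.values()]
    syn = [v[1] for v in defined.values()]
    wil = wilcoxon_signed_rank(list(zip(syn, two)))
    return {
        "mean_kappa": {"two_sequence": float(np.mean(two)),
                       "synthetic_protocol": float(np.mean(syn))},
        "wilcoxon": wil,
    }


def _attach_ground_truth(records: pd.DataFrame) -> pd.DataFrame:
    required = {"dataset_id", "reader_id", "protocol", "pathology", "grade"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"grading table missing columns: {sorted(missing_cols)}")
    reads = records[records.protocol.isin(PROTOCOLS)].copy()
    if "gt_grade" in records.columns and records.gt_grade.notna().all():
        return reads
    gt = records[records.protocol == "ground_truth"]
    if gt.empty:
        raise ValueError("no ground truth: provide a gt_grade column or "
                         "protocol='ground_truth' rows")
    gt_map = gt.set_index(["dataset_id", "pathology"]).grade
    reads["gt_grade"] = [
        gt_map.get((d, k), np.nan)
        for d, k in zip(reads.dataset_id, reads.pathology)]
    if reads.gt_grade.isna().any():
        bad = sorted(reads.loc[reads.gt_grade.isna(), "dataset_id"].unique().tolist())
        raise ValueError(f"ground truth missing for datasets: {bad}")
    return reads


def summarize_study(records: pd.DataFrame) -> AgreementReport:
    """Full study summary from a long-format grading table.

    Expects one row per (dataset, reader, protocol, pathology) with columns
    ``dataset_id, reader_id, protocol, pathology, grade`` and ground truth
    either as a ``gt_grade`` column or as ``protocol='ground_truth'`` rows.
    Readers are pooled as independent rows. Produces per-pathology kappa
    (with CI) and accuracy under each protocol, mean kappa per protocol, the
    Wilcoxon test on the pathology-wise kappa pairs, and per-pathology
    McNemar tests on correctness.
    """
    reads = _attach_ground_truth(records)
    kinds = [k for k in PATHOLOGY_KINDS if k in set(reads.pathology)]
    if not kinds:
        kinds = sorted(set(reads.pathology))
    report = AgreementReport()
    kappa_pairs: dict[str, tuple[float, float]] = {}
    for kind in kinds:
        sub = reads[reads.pathology == kind]
        entry: dict = {}
        for proto in PROTOCOLS:
            ps = sub[sub.protocol == proto].sort_values(["dataset_id", "reader_id"])
            if ps.empty:
                raise ValueError(f"no {proto} gradings for {kind}")
            kr = cohens_kappa(ps.grade.to_numpy(), ps.gt_grade.to_numpy())
            entry[proto] = {"kappa": kr,
                            "accuracy": grading_accuracy(ps.grade, ps.gt_grade),
                            "n": len(ps)}
        report.per_pathology[kind] = entry
        kappa_pairs[kind] = (entry["two_sequence"]["kappa"].kappa,
                             entry["synthetic_protocol"]["kappa"].kappa)

        two = sub[sub.protocol == "two_sequence"].sort_values(
            ["dataset_id", "reader_id"])
        syn = sub[sub.protocol == "synthetic_protocol"].sort_values(
            ["dataset_id", "reader_id"])
        if len(two) == len(syn):
            report.mcnemar[kind] = mcnemar_test(
                (syn.grade == syn.gt_grade).to_numpy(),
                (two.grade == two.gt_grade).to_numpy())

    agg = aggregate_kappa_pairs(kappa_pairs)
    report.mean_kappa = agg["mean_kappa"]
    report.wilcoxon = agg["wilcoxon"]
    return report


def read_grading_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df


def write_report(report: AgreementReport, path) -> None:
    from pathlib import Path
    Path(path).write_text(report.to_json())
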