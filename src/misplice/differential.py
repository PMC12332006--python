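"""Differential mis-splicing statistics and calling rules.

Two calling paths are provided, mirroring the two analysis pipelines:

* the MSI path: per-intron Welch t-test on replicate MSI values with a
  minimum delta, used for gene-level event categories;
* the IR-ratio path: Audic-Claverie test on pooled counts, BH FDR, and the
  four-rule differential-retention filter (FDR <= 0.05, 100% coverage in the
  gaining condition, >=10% IR ratio there, and >=5% IR ratio over the other
  condition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from misplice.catalog import IntronRecord

#: p-value sentinel for zero-variance groups with unequal means
P_SENTINEL = 5e-324


@dataclass
class ConditionDesign:
    """Two-condition design: labels plus the sample->condition map."""

    treated: str
    control: str
    sample_to_condition: dict[str, str]

    def __post_init__(self) -> None:
        labels = {self.treated, self.control}
        for sample, cond in self.sample_to_condition.items():
            if cond not in labels:
                raise ValueError(f"sample {sample!r} mapped to unknown condition {cond!r}")

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.sample_to_condition.items() if c == condition]

    def require_replicates(self, n: int = 2) -> None:
        for cond in (self.treated, self.control):
            if len(self.samples(cond)) < n:
                raise ValueError(f"condition {cond!r} has fewer than {n} samples")

    @classmethod
    def from_table(
        cls, path: str | Path, treated: str | None = None, control: str | None = None
    ) -> "ConditionDesign":
        """Load a design TSV with columns ``sample`` and ``condition``.

        Unless given explicitly, the first condition encountered is treated
        as ``treated`` and the second as ``control``.
        """
        df = pd.read_csv(path, sep="\t")
        mapping = dict(zip(df["sample"].astype(str), df["condition"].astype(str)))
        conds = list(dict.fromkeys(mapping.values()))
        if len(conds) != 2:
            raise ValueError(f"design must have exactly 2 conditions, found {conds}")
        treated = treated or conds[0]
        control = control or next(c for c in conds if c != treated)
        return cls(treated=treated, control=control, sample_to_condition=mapping)


@dataclass
class RetentionRules:
    """Thresholds of the four-rule differential-retention filter."""

    max_fdr: float = 0.05
    min_coverage: float = 1.0
    min_ratio: float = 0.10
    min_delta: float = 0.05


@dataclass
class DiffCall:
    intron_id: str
    intron_class: str
    mean_treated: float
    mean_control: float
    delta: float
    t_stat: float
    df: float
    p_welch: float
    p_ac: float
    fdr: float
    coverage_ok_treated: bool
    coverage_ok_control: bool
    call: str


@dataclass
class GeneEventCategory:
    gene_id: str
    category: str  # IR | AS | IR_and_AS | unaffected | not_detected


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed Welch's t-test (unequal variances).

    Returns (t, Welch-Satterthwaite df, two-tailed p).  Degenerate
    zero-variance-in-both-groups cases: equal means -> (0, df, 1); unequal
    means -> infinite t with a machine-minimum p sentinel.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    dm = a.mean() - b.mean()
    if va == 0 and vb == 0:
        dof = float(na + nb - 2)
        if dm == 0:
            return (0.0, dof, 1.0)
        return (math.copysign(math.inf, dm), dof, P_SENTINEL)
    se2 = va / na + vb / nb
    t = dm / math.sqrt(se2)
    # normalized fractions avoid underflow of se2**2 for tiny variances
    fa, fb = (va / na) / se2, (vb / nb) / se2
    dof = 1.0 / (fa**2 / (na - 1) + fb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return (float(t), float(dof), float(p))


def audic_claverie_pmf(y: int, x: int, n1: float, n2: float) -> float:
    """P(y | x) for libraries of sizes n1 (where x was seen) and n2.

    p(y|x) = (n2/n1)^y * (x+y)! / (x! y! (1+n2/n1)^(x+y+1)).
    """
    r = n2 / n1
    logp = (
        y * math.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(r)
    )
    return float(math.exp(logp))


def audic_claverie_test(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p: 2*min(P(Y<=y|x), P(Y>=y|x)), capped at 1.

    Tail sums are over the conditional law of y given x, which is negative
    binomial with size x+1 and success probability n1/(n1+n2).
    """
    if x != int(x) or y != int(y) or x < 0 or y < 0:
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    x, y = int(x), int(y)
    p = n1 / (n1 + n2)
    lower = float(stats.nbinom.cdf(y, x + 1, p))
    upper = float(stats.nbinom.sf(y - 1, x + 1, p))
    return min(1.0, 2.0 * min(lower, upper))


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, aligned to input order.

    Ties are resolved by a stable sort on (p, input index).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] / (rank / m))
        adjusted[idx] = running
    return adjusted.tolist()


def chi_square_gof(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> tuple[float, int, float]:
    """Chi-square goodness of fit against expected proportions."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected_proportions must have equal length")
    if not math.isclose(props.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("expected proportions must sum to 1")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed total must be positive")
    expected = total * props
    if np.any(expected == 0):
        raise ValueError("expected count of zero")
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    dof = obs.size - 1
    return (chi2, dof, float(stats.chi2.sf(chi2, dof)))


# ---------------------------------------------------------------------------
# calling paths
# ---------------------------------------------------------------------------


def _condition_matrix(
    df: pd.DataFrame, value: str, design: ConditionDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    wide = df.pivot_table(index="intron_id", columns="sample", values=value)
    t_samples = [s for s in design.samples(design.treated) if s in wide.columns]
    c_samples = [s for s in design.samples(design.control) if s in wide.columns]
    return wide[t_samples], wide[c_samples]


def call_missplicing_msi(
    quant_df: pd.DataFrame,
    design: ConditionDesign,
    alpha: float = 0.05,
    min_delta: float = 5.0,
) -> pd.DataFrame:
    """Welch-based IR/AS significance per intron on replicate MSI values.

    ``quant_df`` is the long quant table (intron_id, sample, msi_ret,
    msi_as).  An intron is IR-significant iff Welch p <= alpha and the
    treated-minus-control MSI_ret delta is >= min_delta percentage points;
    AS-significance is the analogue on MSI_AS.
    """
    design.require_replicates(2)
    out = []
    ret_t, ret_c = _condition_matrix(quant_df, "msi_ret", design)
    as_t, as_c = _condition_matrix(quant_df, "msi_as", design)
    for intron_id in ret_t.index:
        row: dict = {"intron_id": intron_id}
        for label, mat_t, mat_c in (("ret", ret_t, ret_c), ("as", as_t, as_c)):
            a = mat_t.loc[intron_id].dropna().to_numpy()
            b = mat_c.loc[intron_id].dropna().to_numpy()
            t, dof, p = welch_t_test(a, b)
            delta = float(a.mean() - b.mean())
            row[f"mean_treated_{label}"] = float(a.mean())
            row[f"mean_control_{label}"] = float(b.mean())
            row[f"delta_{label}"] = delta
            row[f"t_{label}"] = t
            row[f"p_{label}"] = p
            row[f"{'ir' if label == 'ret' else 'as'}_significant"] = bool(
                p <= alpha and delta >= min_delta
            )
        out.append(row)
    return pd.DataFrame(out)


def diff_ir_table(
    quant_df: pd.DataFrame,
    design: ConditionDesign,
    catalog: Iterable[IntronRecord] | None = None,
    fdr_on: str = "ac",
) -> pd.DataFrame:
    """Assemble per-intron differential-retention precursors.

    Means of the IR ratio per condition, Welch t on IR-ratio replicates, an
    Audic-Claverie test on boundary counts pooled across replicates (library
    size = total assigned reads per condition), coverage flags (every
    replicate at 100% intron coverage), and BH FDR over the chosen p-value
    column (``ac`` or ``welch``).
    """
    design.require_replicates(2)
    class_by_id = {i.intron_id: i.intron_class for i in catalog} if catalog is not None else {}
    ir_t, ir_c = _condition_matrix(quant_df, "ir_ratio", design)
    cov_t, cov_c = _condition_matrix(quant_df, "coverage", design)
    pooled = quant_df.assign(boundary=quant_df["n5"] + quant_df["n3"])
    cond = quant_df["sample"].map(design.sample_to_condition)
    lib_sizes = quant_df.groupby(cond)["depth"].sum()
    n1 = float(lib_sizes.get(design.treated, 0)) or 1.0
    n2 = float(lib_sizes.get(design.control, 0)) or 1.0
    boundary_sum = pooled.pivot_table(
        index="intron_id", columns=cond, values="boundary", aggfunc="sum"
    )
    rows = []
    for intron_id in ir_t.index:
        a = ir_t.loc[intron_id].dropna().to_numpy()
        b = ir_c.loc[intron_id].dropna().to_numpy()
        t, dof, p_w = welch_t_test(a, b)
        x = int(boundary_sum.loc[intron_id].get(design.treated, 0) or 0)
        y = int(boundary_sum.loc[intron_id].get(design.control, 0) or 0)
        rows.append(
            {
                "intron_id": intron_id,
                "intron_class": class_by_id.get(intron_id, "unclassified"),
                "mean_treated": float(a.mean()),
                "mean_control": float(b.mean()),
                "delta": float(a.mean() - b.mean()),
                "t_stat": t,
                "df": dof,
                "p_welch": p_w,
                "p_ac": audic_claverie_test(x, y, n1, n2),
                "coverage_ok_treated": bool((cov_t.loc[intron_id].dropna() >= 1.0).all()),
                "coverage_ok_control": bool((cov_c.loc[intron_id].dropna() >= 1.0).all()),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        pcol = {"ac": "p_ac", "welch": "p_welch"}[fdr_on]
        table["fdr"] = bh_fdr(table[pcol].tolist())
    return table


def call_differential_retention(
    table: pd.DataFrame, rules: RetentionRules | None = None
) -> pd.DataFrame:
    """Apply the four-rule filter to a differential-retention table.

    Requires columns mean_treated, mean_control, coverage_ok_treated,
    coverage_ok_control, fdr.  Rows with any of these missing are excluded
    with a log entry.  Adds a ``call`` column with values
    retained_in_treated / retained_in_control / not_significant.
    """
    import logging

    rules = rules or RetentionRules()
    needed = ["mean_treated", "mean_control", "coverage_ok_treated", "coverage_ok_control", "fdr"]
    missing = table[needed].isna().any(axis=1)
    if missing.any():
        logging.getLogger(__name__).warning(
            "excluding %d introns with missing predicate inputs", int(missing.sum())
        )
    table = table.loc[~missing].copy()
    calls = []
    for row in table.itertuples():
        call = "not_significant"
        if row.fdr <= rules.max_fdr:
            if (
                row.coverage_ok_treated
                and row.mean_treated >= rules.min_ratio
                and row.mean_treated - row.mean_control >= rules.min_delta
            ):
                call = "retained_in_treated"
            elif (
                row.coverage_ok_control
                and row.mean_control >= rules.min_ratio
                and row.mean_control - row.mean_treated >= rules.min_delta
            ):
                call = "retained_in_control"
        calls.append(call)
    table["call"] = calls
    return table


def categorize_genes(
    calls: pd.DataFrame, catalog: Iterable[IntronRecord]
) -> tuple[list[GeneEventCategory], dict[str, int]]:
    """Gene-level event categories from per-intron MSI significance calls.

    ``calls`` needs intron_id, ir_significant, as_significant.  Genes in the
    catalog with no intron present in ``calls`` are ``not_detected``.
    Returns the per-gene list and a count summary over detected genes.
    """
    catalog = list(catalog)
    gene_by_intron = {i.intron_id: i.gene_id for i in catalog}
    all_genes = {i.gene_id for i in catalog}
    ir_genes: set[str] = set()
    as_genes: set[str] = set()
    detected: set[str] = set()
    for row in calls.itertuples():
        gene = gene_by_intron.get(row.intron_id)
        if gene is None:
            continue
        detected.add(gene)
        if row.ir_significant:
            ir_genes.add(gene)
        if row.as_significant:
            as_genes.add(gene)
    result = []
    counts = {"IR": 0, "AS": 0, "IR_and_AS": 0, "unaffected": 0, "detected": len(detected)}
    for gene in sorted(all_genes):
        if gene not in detected:
            result.append(GeneEventCategory(gene, "not_detected"))
            continue
        if gene in ir_genes and gene in as_genes:
            cat = "IR_and_AS"
        elif gene in ir_genes:
            cat = "IR"
        elif gene in as_genes:
            cat = "AS"
        else:
            cat = "unaffected"
        counts[cat] += 1
        result.append(GeneEventCategory(gene, cat))
    return result, counts


def _transcript_orders(catalog: list[IntronRecord]) -> dict[str, list[IntronRecord]]:
    """Per-transcript intron lists ordered 5'->3' in transcript orientation."""
    per_tx: dict[str, list[IntronRecord]] = {}
    for intron in catalog:
        for tx in intron.transcript_ids:
            per_tx.setdefault(tx, []).append(intron)
    for tx, introns in per_tx.items():
        reverse = introns[0].strand == "-"
        introns.sort(key=lambda i: i.start, reverse=reverse)
    return per_tx


def flanking_major_ir(
    catalog: Iterable[IntronRecord], retained: Mapping[str, bool] | set[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flanking-major-intron analysis around retained minor introns.

    ``retained`` flags retained introns by id (set or id->bool map).  The
    table lists, for each retained minor intron and transcript, its
    immediately adjacent introns and their class/retention.  The summary
    reports what fraction of retained major introns flank a retained minor
    intron (ordinal adjacency within a shared transcript).
    """
    catalog = list(catalog)
    if isinstance(retained, set):
        retained_ids = retained
    else:
        retained_ids = {k for k, v in retained.items() if v}
    per_tx = _transcript_orders(catalog)
    rows = []
    flanking_major: set[str] = set()
    for tx, introns in per_tx.items():
        for pos, intron in enumerate(introns):
            if intron.intron_class != "minor" or intron.intron_id not in retained_ids:
                continue
            for side, other_pos in (("upstream", pos - 1), ("downstream", pos + 1)):
                if 0 <= other_pos < len(introns):
                    other = introns[other_pos]
                    rows.append(
                        {
                            "minor_intron": intron.intron_id,
                            "transcript_id": tx,
                            "side": side,
                            "flank_intron": other.intron_id,
                            "flank_class": other.intron_class,
                            "flank_retained": other.intron_id in retained_ids,
                        }
                    )
                    if other.intron_class == "major" and other.intron_id in retained_ids:
                        flanking_major.add(other.intron_id)
                else:
                    rows.append(
                        {
                            "minor_intron": intron.intron_id,
                            "transcript_id": tx,
                            "side": side,
                            "flank_intron": None,
                            "flank_class": "absent",
                            "flank_retained": False,
                        }
                    )
    retained_major = {
        i.intron_id for i in catalog if i.intron_class == "major" and i.intron_id in retained_ids
    }
    n_major = len(retained_major)
    n_flanking = len(flanking_major & retained_major)
    summary = {
        "n_retained_major": n_major,
        "n_flanking": n_flanking,
        "frac_flanking": n_flanking / n_major if n_major else 0.0,
        "frac_nonflanking": (n_major - n_flanking) / n_major if n_major else 0.0,
    }
    return pd.DataFrame(rows), summary
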