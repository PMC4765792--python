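"""Subgenome expression partitioning and heredity of miRNA expression.

Expression of a mature miRNA in a library is the summed count of reads whose
alignment lies within the mature's genomic span (with a small configurable
slack), normalized to reads per million (RPM = count / clean reads * 1e6).
A read mapping inside mature spans on both subgenomes is counted in full on
BOTH subgenome tallies — the double-counting rule for indistinguishable
homeolog reads.

The partition test compares per-mature RPM between the A and C subgenomes
with a two-sided Wilcoxon rank-sum test (exact for small groups), and the
headline statistic is total RPM per unique mature sequence (or per Mb of
subgenome).  Heredity in derived homozygous lines is classified against the
mid-parent value: at least a twofold deviation of the derived-line mean is
non-additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import compute_rpm
from .seqio import Alignment, GenomeSet, SmallRNALibrary

PSEUDOCOUNT_RPM = 0.1   # epsilon added to both sides of every fold change


@dataclass
class MatureSpan:
    """Genomic span of one mature miRNA (0-based half-open)."""

    mature: str
    locus_id: str
    chromosome: str
    start: int
    end: int
    subgenome: str


@dataclass
class PartitionResult:
    mode: str               # per_mature | per_mb
    mean_a: float
    mean_c: float
    ratio: float            # C / A
    p_value: float
    test_name: str
    library_set: str
    environment: str


@dataclass
class HeredityCall:
    mature: str
    mid_parent: float
    derived_mean: float
    log2_deviation: float
    call: str               # additive | non-additive


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_mature_reads(
    library: SmallRNALibrary,
    spans: list[MatureSpan],
    alignments: dict[str, list[Alignment]],
    slack: int = 2,
) -> pd.DataFrame:
    """One expression-matrix column: counts and RPM per mature miRNA.

    A read contributes its full count to a mature when one of its alignments
    lies within the mature's span extended by ``slack`` nt on each side.  A
    read matching matures on both subgenomes contributes its full count to
    both (counted twice).  Rows are indexed by mature sequence; a mature
    carried by loci on both subgenomes appears once per subgenome.
    """
    by_chrom: dict[str, list[MatureSpan]] = {}
    for sp in spans:
        by_chrom.setdefault(sp.chromosome, []).append(sp)
    starts = {
        c: np.array([sp.start for sp in v]) for c, v in by_chrom.items()
    }
    rows: dict[tuple[str, str], dict] = {}
    for sp in spans:
        rows[(sp.mature, sp.subgenome)] = {
            "mature": sp.mature, "subgenome": sp.subgenome,
            "locus_id": sp.locus_id, "count": 0,
        }
    for read, alns in alignments.items():
        count = library.unique_reads.get(read, 0)
        if not count or not alns:
            continue
        hit_keys: set[tuple[str, str]] = set()
        for a in alns:
            for sp in by_chrom.get(a.chromosome, []):
                if a.start >= sp.start - slack and a.end <= sp.end + slack:
                    hit_keys.add((sp.mature, sp.subgenome))
        for key in hit_keys:
            rows[key]["count"] += count
    df = pd.DataFrame(rows.values())
    if df.empty:
        df = pd.DataFrame(columns=["mature", "subgenome", "locus_id", "count"])
    df["rpm"] = [
        compute_rpm(int(c), library.clean_read_total) for c in df["count"]
    ]
    df["library_id"] = library.library_id
    return df


def expression_matrix(
    libraries: list[SmallRNALibrary],
    spans: list[MatureSpan],
    alignments: dict[str, list[Alignment]],
    slack: int = 2,
) -> pd.DataFrame:
    """Long-format expression matrix over libraries (one row per mature x
    subgenome x library)."""
    cols = [count_mature_reads(lib, spans, alignments, slack) for lib in libraries]
    return pd.concat(cols, ignore_index=True)


# ---------------------------------------------------------------------------
# partition statistics
# ---------------------------------------------------------------------------

def rank_sum_test(a: np.ndarray, c: np.ndarray) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p-value; exact enumeration for groups of
    at most 10, normal approximation otherwise."""
    method = "exact" if max(len(a), len(c)) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(a, c, alternative="two-sided", method=method)
    return float(res.pvalue), f"wilcoxon-rank-sum ({method})"


def subgenome_partition_test(
    matrix: pd.DataFrame,
    genome: GenomeSet | None = None,
    mode: str = "per_mature",
    library_set: str = "",
    environment: str = "",
) -> PartitionResult:
    """Compare miRNA expression between the A and C subgenomes.

    ``per_mature``: total RPM divided by the number of unique mature
    sequences, per subgenome.  ``per_mb``: total RPM divided by the
    subgenome length in Mb (requires ``genome``).  The p-value always comes
    from the rank-sum test on per-mature RPM totals A vs C.
    """
    if mode not in ("per_mature", "per_mb"):
        raise ValueError(f"unknown mode {mode!r}")
    per_mature = (
        matrix.groupby(["mature", "subgenome"], as_index=False)["rpm"].sum()
    )
    a_vals = per_mature.loc[per_mature["subgenome"] == "A", "rpm"].to_numpy()
    c_vals = per_mature.loc[per_mature["subgenome"] == "C", "rpm"].to_numpy()
    if len(a_vals) < 2 or len(c_vals) < 2:
        raise ValueError("need at least 2 mature miRNAs per subgenome")
    if mode == "per_mature":
        mean_a = float(a_vals.sum() / len(a_vals))
        mean_c = float(c_vals.sum() / len(c_vals))
    else:
        if genome is None:
            raise ValueError("per_mb mode requires the genome")
        mb_a = genome.subgenome_length("A") / 1e6
        mb_c = genome.subgenome_length("C") / 1e6
        if mb_a == 0 or mb_c == 0:
            raise ValueError("zero-length subgenome")
        mean_a = float(a_vals.sum() / mb_a)
        mean_c = float(c_vals.sum() / mb_c)
    p, test_name = rank_sum_test(a_vals, c_vals)
    return PartitionResult(
        mode=mode, mean_a=mean_a, mean_c=mean_c,
        ratio=mean_c / mean_a, p_value=p, test_name=test_name,
        library_set=library_set, environment=environment,
    )


def exact_permutation_pvalue(a: np.ndarray, c: np.ndarray) -> float:
    """Two-sided permutation p-value of the rank-sum statistic by full
    enumeration of group assignments (small n only)."""
    pooled = np.concatenate([a, c])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    obs = ranks[: len(a)].sum()
    mean = len(a) * (n + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n), len(a)):
        s = ranks[list(idx)].sum()
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            count += 1
        total += 1
    return count / total


def mirna_density(loci: list, genome: GenomeSet) -> dict[str, float]:
    """MIRNA loci per Mb for each subgenome."""
    out = {}
    for sub in ("A", "C"):
        length_mb = genome.subgenome_length(sub) / 1e6
        if length_mb == 0:
            raise ValueError(f"zero-length subgenome {sub}")
        n = sum(1 for l in loci if getattr(l, "subgenome", None) == sub)
        out[sub] = n / length_mb
    return out


# ---------------------------------------------------------------------------
# differential expression and heredity
# ---------------------------------------------------------------------------

def _fold_ratio(num, den, epsilon: float):
    """Fold change with a pseudo-count only where a zero would otherwise
    make the ratio undefined or infinite, so exact twofold boundaries on
    positive values stay exact."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    clean = (num > 0) & (den > 0)
    return np.where(clean, num / np.where(den > 0, den, 1.0),
                    (num + epsilon) / (den + epsilon))


def _group_means(matrix: pd.DataFrame, library_ids: list[str]) -> pd.Series:
    sub = matrix[matrix["library_id"].isin(library_ids)]
    wide = sub.pivot_table(
        index=["mature", "subgenome"], columns="library_id", values="rpm",
        aggfunc="sum", fill_value=0.0,
    )
    for lib in library_ids:          # libraries with no counted reads at all
        if lib not in wide.columns:
            wide[lib] = 0.0
    return wide[library_ids].mean(axis=1)


def differential_expression(
    matrix: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    fold: float = 2.0,
    epsilon: float = PSEUDOCOUNT_RPM,
) -> pd.DataFrame:
    """Fold-change DE table between two library groups.

    DE iff the (pseudo-counted) fold change is strictly above ``fold`` or
    strictly below 1/``fold``.
    """
    if not group1 or not group2:
        raise ValueError("both library groups must be non-empty")
    m1 = _group_means(matrix, group1)
    m2 = _group_means(matrix, group2)
    df = pd.DataFrame({"mean1": m1, "mean2": m2}).fillna(0.0)
    fc = _fold_ratio(df["mean1"].to_numpy(), df["mean2"].to_numpy(), epsilon)
    df["fold_change"] = fc
    df["de"] = (fc > fold) | (fc < 1.0 / fold)
    df["direction"] = np.where(fc > 1.0, "up", np.where(fc < 1.0, "down", "equal"))
    return df.reset_index()


def heredity_classification(
    matrix: pd.DataFrame,
    parent1: list[str],
    parent2: list[str],
    derived: list[str],
    fold: float = 2.0,
    epsilon: float = PSEUDOCOUNT_RPM,
) -> tuple[list[HeredityCall], dict]:
    """Classify each miRNA's heredity in derived lines as additive or
    non-additive relative to the mid-parent value (MPV).

    Non-additive iff derived mean >= fold * MPV or <= MPV / fold (the
    twofold threshold is inclusive), evaluated with a pseudo-count on both
    terms.
    """
    if not (parent1 and parent2 and derived):
        raise ValueError("parent and derived library sets must be non-empty")
    p1 = _group_means(matrix, parent1)
    p2 = _group_means(matrix, parent2)
    dm = _group_means(matrix, derived)
    df = pd.DataFrame({"p1": p1, "p2": p2, "derived": dm}).fillna(0.0)
    calls: list[HeredityCall] = []
    for (mature, _sub), row in df.iterrows():
        mpv = 0.5 * (row["p1"] + row["p2"])
        dev = float(_fold_ratio(row["derived"], mpv, epsilon))
        log2dev = float(np.log2(dev))
        call = "non-additive" if (dev >= fold or dev <= 1.0 / fold) else "additive"
        calls.append(HeredityCall(
            mature=mature, mid_parent=float(mpv),
            derived_mean=float(row["derived"]),
            log2_deviation=log2dev, call=call,
        ))
    n_non = sum(1 for c in calls if c.call == "non-additive")
    n_add = len(calls) - n_non
    summary = {
        "n_total": len(calls),
        "n_non_additive": n_non,
        "n_additive": n_add,
        "ratio_non_additive": n_non / len(calls) if calls else float("nan"),
    }
    return calls, summary
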