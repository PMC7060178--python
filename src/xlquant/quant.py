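"""Label-free differential quantitation of cross-link intensities.

Intensity tables hold one row per link and one column per
(condition, replicate) run, plus a per-run target-protein level used for
normalization. Significance follows a fixed fold-change + t-test filter
applied to every configured treated-vs-control comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntensityMatrix",
    "DifferentialConfig",
    "DifferentialResult",
    "read_intensity_table",
    "normalize_to_protein",
    "differential_test",
    "load_table1",
    "apply_table_filter",
    "monolink_report",
]

logger = logging.getLogger(__name__)

PROTEIN_LEVEL_ROW = "__protein__"


@dataclass
class IntensityMatrix:
    """Link intensities (rows) by (condition, replicate) runs (columns)."""

    intensities: pd.DataFrame  # columns: MultiIndex (condition, replicate)
    protein_level: pd.Series  # indexed by (condition, replicate)

    def __post_init__(self) -> None:
        cols = self.intensities.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError("columns must be a (condition, replicate) MultiIndex")
        conditions = cols.get_level_values(0).unique()
        if len(conditions) < 2:
            raise ValueError("need at least two conditions")
        counts = {c: (cols.get_level_values(0) == c).sum() for c in conditions}
        if len(set(counts.values())) != 1:
            raise ValueError(f"unequal replicate counts per condition: {counts}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities")
        if not self.protein_level.index.equals(cols):
            self.protein_level = self.protein_level.reindex(cols)
        if self.protein_level.isna().any() or (self.protein_level <= 0).any():
            bad = self.protein_level[
                self.protein_level.isna() | (self.protein_level <= 0)
            ].index.tolist()
            raise ValueError(f"missing or non-positive protein level for runs {bad}")

    @property
    def conditions(self) -> list[str]:
        return list(self.intensities.columns.get_level_values(0).unique())

    def condition_values(self, condition: str) -> pd.DataFrame:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return self.intensities[condition]


@dataclass(frozen=True)
class DifferentialConfig:
    """The significance filter: fold-change AND p-value, in all comparisons."""

    fc_threshold: float = 1.5
    alpha: float = 0.05
    comparisons: tuple[tuple[str, str], ...] = ()
    require_all_comparisons: bool = True
    log_transform: bool = True
    two_sided: bool = True
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class DifferentialResult:
    link_id: str
    ratios: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    significant: bool
    direction: str  # increase | decrease | none


def read_intensity_table(path: str | Path) -> IntensityMatrix:
    """Read a CSV/TSV with a ``link`` column and ``condition:replicate`` columns.

    A row whose link id is ``__protein__`` carries the per-run protein
    level; if absent, protein levels default to 1 (pre-normalized input).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if "link" not in df.columns:
        raise ValueError(f"{path}: missing 'link' column")
    df = df.set_index("link")
    try:
        columns = pd.MultiIndex.from_tuples(
            [tuple(c.split(":", 1)) for c in df.columns], names=["condition", "replicate"]
        )
    except ValueError as exc:
        raise ValueError(f"{path}: run columns must be 'condition:replicate'") from exc
    df.columns = columns
    if PROTEIN_LEVEL_ROW in df.index:
        protein = df.loc[PROTEIN_LEVEL_ROW]
        df = df.drop(index=PROTEIN_LEVEL_ROW)
    else:
        protein = pd.Series(1.0, index=df.columns)
    return IntensityMatrix(df.astype(float), protein.astype(float))


def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = matrix.intensities.copy()
    df.loc[PROTEIN_LEVEL_ROW] = matrix.protein_level
    out = df.copy()
    out.columns = [f"{c}:{r}" for c, r in df.columns]
    out.index.name = "link"
    out.to_csv(path, sep=sep)


def normalize_to_protein(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide every run's intensities by that run's protein level.

    Idempotent: the protein level is reset to 1 afterwards.
    """
    normalized = matrix.intensities.div(matrix.protein_level, axis=1)
    ones = pd.Series(1.0, index=matrix.intensities.columns)
    return IntensityMatrix(normalized, ones)


def _t_test(treated: np.ndarray, control: np.ndarray, config: DifferentialConfig) -> float:
    if config.log_transform:
        if (treated <= 0).any() or (control <= 0).any():
            return float("nan")
        treated, control = np.log(treated), np.log(control)
    if np.ptp(treated) == 0 and np.ptp(control) == 0:
        # zero variance in both groups: identical means are uninformative
        return 1.0 if treated[0] == control[0] else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = stats.ttest_ind(
            treated, control, equal_var=True,
            alternative="two-sided" if config.two_sided else "greater",
        )
    p = float(result.pvalue)
    return 1.0 if np.isnan(p) else p


def differential_test(
    matrix: IntensityMatrix, config: DifferentialConfig
) -> list[DifferentialResult]:
    """Per-link fold-change ratios and unpaired Student's t-tests.

    A link is significant when ratio >= fc_threshold AND p <= alpha
    (both inclusive) in every configured comparison.
    """
    comparisons = config.comparisons or _default_comparisons(matrix)
    for treated, control in comparisons:
        for name in (treated, control):
            if name not in matrix.conditions:
                raise KeyError(f"comparison condition {name!r} not in matrix")
        if matrix.condition_values(treated).shape[1] < 2:
            raise ValueError("need at least 2 replicates per condition")

    results: list[DifferentialResult] = []
    p_store: list[dict[tuple[str, str], float]] = []
    for link_id, row in matrix.intensities.iterrows():
        ratios: dict[tuple[str, str], float] = {}
        pvals: dict[tuple[str, str], float] = {}
        skip = False
        for treated, control in comparisons:
            tvals = row[treated].to_numpy(dtype=float)
            cvals = row[control].to_numpy(dtype=float)
            if np.isnan(tvals).any() or np.isnan(cvals).any():
                logger.warning("link %s: missing replicate values, excluded", link_id)
                skip = True
                break
            cmean = cvals.mean()
            ratios[(treated, control)] = (
                float(tvals.mean() / cmean) if cmean > 0 else float("inf")
            )
            pvals[(treated, control)] = _t_test(tvals, cvals, config)
        if skip:
            continue
        results.append(
            DifferentialResult(str(link_id), ratios, pvals, significant=False, direction="none")
        )
        p_store.append(pvals)

    if config.bh_correction and results:
        for comp in comparisons:
            raw = np.array([p[comp] for p in p_store])
            adj = _benjamini_hochberg(raw)
            for p, a in zip(p_store, adj):
                p[comp] = float(a)

    final: list[DifferentialResult] = []
    for res, pvals in zip(results, p_store):
        up = all(r >= config.fc_threshold for r in res.ratios.values())
        down = all(r <= 1.0 / config.fc_threshold for r in res.ratios.values())
        low_p = all(p <= config.alpha for p in pvals.values())
        direction = "increase" if up else "decrease" if down else "none"
        final.append(
            DifferentialResult(
                res.link_id, res.ratios, pvals,
                significant=bool(up and low_p), direction=direction,
            )
        )
    return final


def _default_comparisons(matrix: IntensityMatrix) -> tuple[tuple[str, str], ...]:
    conditions = matrix.conditions
    return tuple((conditions[0], c) for c in conditions[1:])


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def load_table1() -> pd.DataFrame:
    """The packaged fixture transcribing the study's printed quantitation table.

    Columns: domain_group, link, ratio_syn_oea, p_syn_oea, ratio_syn_dmso,
    p_syn_dmso — intensity ratios and unpaired t-test p-values (n = 3) for
    the synaptamide/OEA and synaptamide/DMSO comparisons.
    """
    with resources.files("xlquant.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    expected = {
        "domain_group", "link", "ratio_syn_oea", "p_syn_oea", "ratio_syn_dmso", "p_syn_dmso",
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"table1 fixture missing columns {sorted(missing)}")
    return df


def apply_table_filter(
    table: pd.DataFrame, config: DifferentialConfig | None = None
) -> set[str]:
    """Links passing ratio >= fc_threshold and p <= alpha in both comparisons."""
    config = config or DifferentialConfig()
    passing: set[str] = set()
    for _, row in table.iterrows():
        try:
            ok = all(
                float(row[rcol]) >= config.fc_threshold and float(row[pcol]) <= config.alpha
                for rcol, pcol in (
                    ("ratio_syn_oea", "p_syn_oea"),
                    ("ratio_syn_dmso", "p_syn_dmso"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed table row {row.get('link', '?')}: {exc}") from exc
        if ok:
            passing.add(str(row["link"]))
    return passing


def monolink_report(
    matrix: IntensityMatrix, config: DifferentialConfig
) -> list[DifferentialResult]:
    """Differential test over monolink rows (site accessibility changes).

    Rows that are zero in every run are excluded with a warning.
    """
    values = matrix.intensities
    all_zero = (values == 0).all(axis=1)
    if all_zero.any():
        for link_id in values.index[all_zero]:
            logger.warning("monolink %s has zero intensity in all runs; excluded", link_id)
        matrix = IntensityMatrix(values.loc[~all_zero], matrix.protein_level)
    return differential_test(matrix, config)
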