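"""Ordinal coding of categorical survey responses.

Five survey items -- education, employment, health insurance, housing and
income -- are mapped to ordinal ranks ``1..L`` where a higher rank means
greater socioeconomic deprivation.  Income brackets have an unambiguous
order and act as the anchor item; items whose response order is ambiguous
(employment and insurance in particular) are ordered by maximizing their
Spearman correlation with the income ordinal, and whole candidate ordering
schemes are scored by the median of the ten pairwise Spearman correlations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

ITEMS = ("education", "employment", "insurance", "housing", "income")

#: Default response vocabulary per item, listed in deprivation-increasing
#: order (rank 1 = least deprived).  Education, employment, housing and
#: income follow BRFSS response sets; insurance follows NHANES.
DEFAULT_RESPONSE_ORDER: dict[str, list[str]] = {
    "education": [
        "College graduate or advanced degree",
        "Some college or technical school",
        "High school graduate or GED",
        "Grades 9 through 11",
        "Grades 1 through 8",
        "Never attended school",
    ],
    "employment": [
        "Employed for wages",
        "Self-employed",
        "Retired",
        "Homemaker or student",
        "Out of work or unable to work",
    ],
    "insurance": ["Yes", "No"],
    "housing": ["Own", "Rent", "Other arrangement"],
    "income": [
        "$200,000 or more",
        "$150,000 to $199,999",
        "$100,000 to $149,999",
        "$75,000 to $99,999",
        "$50,000 to $74,999",
        "$35,000 to $49,999",
        "$25,000 to $34,999",
        "$10,000 to $24,999",
        "Less than $10,000",
    ],
}

#: Items whose deprivation order is genuinely ambiguous and is refined
#: against the income anchor rather than fixed a priori.
AMBIGUOUS_ITEMS = ("employment", "insurance")


class CodingError(ValueError):
    """Raised for invalid coding tables or unknown response labels."""


@dataclass
class CodingTable:
    """Response-label -> ordinal-rank map for each survey item.

    ``order[item]`` lists the response labels of *item* from least to most
    deprived; the rank of a label is its 1-based position in that list.
    """

    order: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_RESPONSE_ORDER.items()}
    )
    missing_token: str = ""

    def __post_init__(self) -> None:
        if not self.order:
            raise CodingError("coding table is empty")
        for item, labels in self.order.items():
            if len(labels) < 2:
                raise CodingError(f"item {item!r} needs at least 2 response labels")
            if len(set(labels)) != len(labels):
                raise CodingError(f"item {item!r} has duplicate labels")

    @property
    def items(self) -> list[str]:
        return list(self.order)

    def n_levels(self, item: str) -> int:
        return len(self.order[item])

    def rank_of(self, item: str, label: str) -> int:
        return self.order[item].index(label) + 1

    def label_of(self, item: str, rank: int) -> str:
        return self.order[item][rank - 1]

    def with_permutation(self, item: str, permutation: tuple[int, ...]) -> "CodingTable":
        """Return a copy with *item*'s labels reordered by *permutation*.

        ``permutation`` holds 0-based positions into the current order; the
        label at ``permutation[r]`` receives rank ``r + 1``.
        """
        labels = self.order[item]
        if sorted(permutation) != list(range(len(labels))):
            raise CodingError(f"not a permutation of 0..{len(labels) - 1}: {permutation}")
        new_order = {k: list(v) for k, v in self.order.items()}
        new_order[item] = [labels[p] for p in permutation]
        return CodingTable(order=new_order, missing_token=self.missing_token)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"order": self.order, "missing_token": self.missing_token}, fh)

    @classmethod
    def from_yaml(cls, path) -> "CodingTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(order=raw["order"], missing_token=raw.get("missing_token", ""))


@dataclass
class OrderingScheme:
    """One candidate assignment of response orders, with its median-ρ score."""

    scheme_id: str
    permutations: dict[str, tuple[int, ...]]
    score: float | None = None


def encode_responses(raw: pd.DataFrame, coding: CodingTable) -> pd.DataFrame:
    """Encode raw response labels as ordinal ranks (1..L, higher = more deprived).

    Missing entries (NaN or the coding table's missing token) are preserved
    as ``pd.NA``.  Unknown labels raise :class:`CodingError` listing every
    offending label.  Columns with a single observed level are flagged via
    ``result.attrs["constant_columns"]``.
    """
    if raw.empty:
        raise CodingError("empty response table")
    out = pd.DataFrame(index=raw.index)
    unknown: dict[str, set] = {}
    for item in coding.items:
        if item not in raw.columns:
            raise CodingError(f"column {item!r} missing from response table")
        col = raw[item].astype("object").replace(coding.missing_token, np.nan)
        rank_map = {lab: r + 1 for r, lab in enumerate(coding.order[item])}
        encoded = col.map(rank_map)
        bad = set(col.dropna()) - set(rank_map)
        if bad:
            unknown[item] = bad
        out[item] = encoded.astype("Int64")
    if unknown:
        raise CodingError(f"unknown response labels: {unknown}")
    constant = [c for c in out.columns if out[c].dropna().nunique() <= 1]
    if constant:
        logger.warning("constant survey columns: %s", constant)
    out.attrs["constant_columns"] = constant
    if "participant_id" in raw.columns:
        out.insert(0, "participant_id", raw["participant_id"])
    return out


def decode_responses(table: pd.DataFrame, coding: CodingTable) -> pd.DataFrame:
    """Inverse of :func:`encode_responses`: ranks back to raw labels."""
    out = pd.DataFrame(index=table.index)
    for item in coding.items:
        out[item] = table[item].map(
            lambda r: coding.label_of(item, int(r)) if pd.notna(r) else np.nan
        )
    return out


def _pairwise_spearman(x: pd.Series, y: pd.Series, min_pairs: int = 3) -> float:
    mask = x.notna() & y.notna()
    if mask.sum() < min_pairs:
        return np.nan
    xv = x[mask].astype(float).to_numpy()
    yv = y[mask].astype(float).to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return np.nan
    return float(stats.spearmanr(xv, yv).statistic)


def spearman_matrix(table: pd.DataFrame, items: list[str] | None = None) -> pd.DataFrame:
    """Tie-corrected Spearman correlations on pairwise-complete observations.

    Undefined pairs (all-missing overlap or a constant column) are NaN and
    listed in ``result.attrs["undefined_pairs"]``.
    """
    items = items or [c for c in table.columns if c in ITEMS]
    if len(items) < 2:
        raise ValueError("need at least two items")
    mat = pd.DataFrame(np.eye(len(items)), index=items, columns=items)
    undefined = []
    for a, b in itertools.combinations(items, 2):
        rho = _pairwise_spearman(table[a], table[b])
        if np.isnan(rho):
            undefined.append((a, b))
        mat.loc[a, b] = mat.loc[b, a] = rho
    mat.attrs["undefined_pairs"] = undefined
    return mat


def refine_ordering_against_income(
    table: pd.DataFrame,
    item: str,
    candidate_permutations: list[tuple[int, ...]],
    coding: CodingTable | None = None,
    income_item: str = "income",
) -> tuple[tuple[int, ...], pd.DataFrame]:
    """Pick the response order of *item* maximizing Spearman ρ with income.

    ``candidate_permutations`` are 0-based reorderings of the item's current
    rank order.  Ties are broken by the lexicographically smallest
    permutation and reported as ambiguous via ``scores.attrs["ambiguous"]``.
    Returns ``(best_permutation, score_table)``.
    """
    if not candidate_permutations:
        raise ValueError("no candidate permutations supplied")
    if table[income_item].notna().sum() < 3:
        raise ValueError("income column too incomplete to anchor ordering")
    scores = []
    for perm in candidate_permutations:
        # rank r in the current order becomes position of (r-1) in perm, +1
        new_rank = {p + 1: r + 1 for r, p in enumerate(perm)}
        recoded = table[item].map(lambda v: new_rank[int(v)] if pd.notna(v) else np.nan)
        scores.append(_pairwise_spearman(recoded, table[income_item]))
    score_df = pd.DataFrame({"permutation": candidate_permutations, "spearman_vs_income": scores})
    best = np.nanmax(score_df["spearman_vs_income"].to_numpy())
    tied = [
        tuple(p)
        for p, s in zip(candidate_permutations, scores)
        if np.isclose(s, best, atol=1e-12, equal_nan=False)
    ]
    ambiguous = len(tied) > 1
    if ambiguous:
        logger.warning("ordering of %r ambiguous: %d tied candidates", item, len(tied))
    score_df.attrs["ambiguous"] = ambiguous
    return min(tied), score_df


def score_scheme(table_raw: pd.DataFrame, coding: CodingTable, scheme: OrderingScheme) -> float:
    """Median of the ten off-diagonal pairwise Spearman values under *scheme*."""
    applied = coding
    for item, perm in scheme.permutations.items():
        applied = applied.with_permutation(item, perm)
    encoded = encode_responses(table_raw, applied)
    mat = spearman_matrix(encoded, applied.items)
    tri = mat.to_numpy()[np.triu_indices(len(applied.items), k=1)]
    return float(np.nanmedian(tri))


def select_ordering_scheme(
    table_raw: pd.DataFrame, coding: CodingTable, schemes: list[OrderingScheme]
) -> tuple[OrderingScheme, pd.DataFrame]:
    """Score every scheme and return the one with the highest median ρ.

    Ties go to the first-listed scheme and are logged.  Returns the winning
    scheme (score filled in) and the full score table.
    """
    if not schemes:
        raise ValueError("no ordering schemes supplied")
    for scheme in schemes:
        scheme.score = score_scheme(table_raw, coding, scheme)
    scores = np.array([s.score for s in schemes])
    best_idx = int(np.nanargmax(scores))
    if np.sum(np.isclose(scores, scores[best_idx])) > 1:
        logger.warning("ordering-scheme tie at median rho=%.4f; first listed wins", scores[best_idx])
    report = pd.DataFrame(
        {"scheme_id": [s.scheme_id for s in schemes], "median_spearman": scores}
    )
    return schemes[best_idx], report


def default_candidate_schemes(coding: CodingTable | None = None) -> list[OrderingScheme]:
    """Candidate orderings varying the ambiguous items (employment, insurance).

    Employment: identity, retired-last, and self-employed/retired swapped;
    insurance: identity and reversed — six schemes in all.
    """
    coding = coding or CodingTable()
    n_emp = coding.n_levels("employment")
    emp_perms = [
        tuple(range(n_emp)),
        (0, 1, 3, 4, 2)[:n_emp] if n_emp == 5 else tuple(range(n_emp)),
        (1, 0, 2, 3, 4)[:n_emp] if n_emp == 5 else tuple(range(n_emp))[::-1],
    ]
    ins_perms = [(0, 1), (1, 0)]
    schemes = []
    for i, (ep, ip) in enumerate(itertools.product(emp_perms, ins_perms), start=1):
        schemes.append(
            OrderingScheme(
                scheme_id=f"scheme_{i}", permutations={"employment": ep, "insurance": ip}
            )
        )
    return schemes
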