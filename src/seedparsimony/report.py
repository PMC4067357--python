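"""Tabular reports (pandas DataFrames, serialized as TSV).

Layouts mirror the tables such analyses conventionally publish: a
per-character homoplasy table (CI/RI/RC), an ensemble statistics table, and
a phylogenetic-signal table (observed steps, permutation count, P).
Numbers are kept at full precision here; callers round at presentation time.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import pandas as pd

from .inference import PermutationResult, WilcoxonResult
from .matrix import CharacterMatrix
from .parsimony import FitIndices


def fit_indices_table(
    fi: FitIndices, characters: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    n = len(fi.s)
    labels = list(characters) if characters is not None else [
        f"char{j + 1}" for j in range(n)
    ]
    rows = []
    for j in range(n):
        rows.append(
            {
                "character": labels[j],
                "m": int(fi.m[j]),
                "s": int(fi.s[j]),
                "g": int(fi.g[j]),
                "CI": fi.ci[j],
                "RI": fi.ri[j],
                "RC": fi.rc[j],
                "note": fi.excluded[j] or "",
            }
        )
    rows.append(
        {
            "character": "ensemble",
            "m": int(fi.m.sum()),
            "s": int(fi.s.sum()),
            "g": int(fi.g.sum()),
            "CI": fi.ensemble_ci,
            "RI": fi.ensemble_ri,
            "RC": fi.ensemble_rc,
            "note": f"multistate_mode={fi.multistate_mode}",
        }
    )
    return pd.DataFrame(rows)


def ensemble_statistics_table(matrix: CharacterMatrix, fi: FitIndices) -> pd.DataFrame:
    s = matrix.summary()
    rows = [
        ("Tree length", fi.tree_length),
        ("Aligned length", s.n_characters),
        ("Variable sites (proportion)", s.n_variable_characters / s.n_characters),
        ("Parsimony informative sites (proportion)",
         s.n_informative_characters / s.n_characters),
        ("Ensemble consistency index", fi.ensemble_ci),
        ("Ensemble retention index", fi.ensemble_ri),
        ("Rescaled consistency index", fi.ensemble_rc),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def signal_table(
    results: List[PermutationResult], characters: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    rows = []
    for r in results:
        label = (
            characters[r.character]
            if characters is not None and r.character is not None
            else f"char{(r.character or 0) + 1}"
        )
        rows.append(
            {
                "character": label,
                "observed_steps": r.observed_steps,
                "count_le": r.count_le,
                "P": r.p,
                "significant": r.p < 0.05,
            }
        )
    return pd.DataFrame(rows)


def templeton_table(results: List[tuple]) -> pd.DataFrame:
    """Rows of (hypothesis name, WilcoxonResult) pairs."""
    rows = []
    for name, w in results:
        rows.append(
            {
                "hypothesis": name,
                "delta_length": w.delta,
                "n_nonzero": w.n_nonzero,
                "T": w.t_statistic,
                "z": w.z,
                "P": w.p,
                "P_exact": w.p_exact,
                "outcome": "Reject" if w.p < 0.05 else "Cannot reject",
            }
        )
    return pd.DataFrame(rows)
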