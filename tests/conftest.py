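"""Shared fixtures: small cohorts, target lists and an isotope oracle."""

from __future__ import annotations

import logging
import math

import numpy as np
import pytest

from hilipid import (
    CellLine,
    PipelineConfig,
    SampleRecord,
    generate_target_list,
)
from hilipid.lipid_chem import ISOTOPE_ABUNDANCE, ElementalFormula

logging.getLogger("hilipid").setLevel(logging.ERROR)


# ---------------------------------------------------------------------------
# Independent isotope-pattern oracle: explicit enumeration of per-element
# isotope compositions with multinomial weights.  Deliberately structured
# differently from the implementation (no truncated polynomial powering).
# ---------------------------------------------------------------------------

def _compositions(n: int, k: int):
    """All ways to place n atoms into k isotope slots."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)


def enumeration_pattern(formula: ElementalFormula, n_max: int = 5) -> np.ndarray:
    """Aggregated isotopologue fractions by exhaustive composition enumeration."""
    per_element = []
    for el, count in formula.counts().items():
        if count == 0:
            continue
        dist = ISOTOPE_ABUNDANCE[el]
        k = len(dist)
        shifts = {}
        for comp in _compositions(count, k):
            shift = sum(i * c for i, c in enumerate(comp))
            if shift > n_max:
                continue
            coeff = math.factorial(count)
            for c in comp:
                coeff //= math.factorial(c)
            weight = float(coeff)
            for c, p in zip(comp, dist):
                weight *= p ** c
            shifts[shift] = shifts.get(shift, 0.0) + weight
        per_element.append(shifts)
    total = {0: 1.0}
    for shifts in per_element:
        nxt: dict[int, float] = {}
        for s1, w1 in total.items():
            for s2, w2 in shifts.items():
                if s1 + s2 <= n_max:
                    nxt[s1 + s2] = nxt.get(s1 + s2, 0.0) + w1 * w2
        total = nxt
    out = np.zeros(n_max + 1)
    for s, w in total.items():
        out[s] = w
    return out


@pytest.fixture(scope="session")
def oracle_pattern():
    return enumeration_pattern


@pytest.fixture(scope="session")
def targets():
    return generate_target_list()


@pytest.fixture(scope="session")
def tiny_config(tmp_path_factory):
    """Two lines, 2x2 replicates: the smallest design the aggregation accepts."""
    out = tmp_path_factory.mktemp("tiny_cohort")
    return PipelineConfig(
        outdir=str(out), seed=11,
        lines=("WT", "MFN12_KO"), n_biological=2, n_extraction=2,
    )


@pytest.fixture(scope="session")
def wt_sample():
    return SampleRecord(CellLine.WT, 1, 1)
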