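import numpy as np
import pandas as pd
import pytest

from prmlfq import AbundanceMatrix, CalibrationSeries, SampleMetadata


def make_matrix(values, sample_ids=None, unique_peptides=None, lengths=None):
    """Build a small AbundanceMatrix from a dict protein -> list of values."""
    proteins = list(values)
    n = len(values[proteins[0]])
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    grid = pd.DataFrame(
        {s: [values[p][j] for p in proteins] for j, s in enumerate(sample_ids)},
        index=proteins,
    )
    meta = pd.DataFrame(
        {
            "unique_peptides": unique_peptides or {p: 3 for p in proteins},
            "length_aa": lengths or {p: 300 for p in proteins},
            "description": {p: "" for p in proteins},
        }
    ).loc[proteins]
    return AbundanceMatrix(intensity=grid, protein_meta=meta)


def make_metadata(groups_by_sample):
    """SampleMetadata from sample_id -> group."""
    table = pd.DataFrame(
        {
            "patient_id": [f"pt_{s}" for s in groups_by_sample],
            "group": list(groups_by_sample.values()),
        },
        index=pd.Index(list(groups_by_sample), name="sample_id"),
    )
    return SampleMetadata(table=table)


def make_series(slope=0.02, intercept=0.0, levels=None, reps=3, peptide="pep1",
                blank_conc=(0.0, 0.0), noise=None, sis=50.0):
    """Noise-free (or perturbed) calibration series on an exact line."""
    levels = np.asarray(
        levels if levels is not None else np.geomspace(0.41, 250.0, 7)
    )
    ratios = []
    for k, x in enumerate(levels):
        r = np.full(reps, slope * x + intercept)
        if noise is not None:
            r = r * (1.0 + np.asarray(noise[k]))
        ratios.append(r)
    blanks = slope * np.asarray(blank_conc, dtype=float) + intercept
    return CalibrationSeries(
        peptide_id=peptide, level_fmol=levels, ratios=ratios,
        blank_ratios=blanks, sis_fmol=sis,
    )


@pytest.fixture
def two_group_meta():
    return make_metadata(
        {**{f"a{i}": "pure_DCIS" for i in range(1, 16)},
         **{f"b{i}": "pure_IDC" for i in range(1, 16)}}
    )
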