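import numpy as np
import pandas as pd
import pytest

from demosfs.spectra import VariantTable


def make_table(rows, popmap):
    """rows: (contig, pos, qual, annotation, dosages...)"""
    samples = list(popmap)
    recs = []
    for contig, pos, qual, ann, dosages in rows:
        rec = {"contig": contig, "pos": pos, "ref": "A", "alt": "G",
               "qual": qual, "annotation": ann}
        rec.update(dict(zip(samples, dosages)))
        recs.append(rec)
    df = pd.DataFrame(recs, columns=["contig", "pos", "ref", "alt", "qual",
                                     "annotation"] + samples)
    return VariantTable(df, dict(popmap))


POPMAP6 = {"MOJ_0": "MOJ", "MOJ_1": "MOJ", "SIN_0": "SIN", "SIN_1": "SIN",
           "SON_0": "SON", "SON_1": "SON"}


@pytest.fixture
def popmap6():
    return dict(POPMAP6)


@pytest.fixture
def toy_table(popmap6):
    """Five clean synonymous sites on two contigs, complete genotypes."""
    rows = [
        ("c1", 1, 35.0, "synonymous", (1, 0, 0, 0, 0, 0)),
        ("c1", 2, 40.0, "synonymous", (0, 1, 1, 0, 0, 0)),
        ("c1", 3, 25.0, "synonymous", (2, 2, 0, 1, 0, 0)),
        ("c2", 1, 50.0, "synonymous", (0, 0, 0, 0, 1, 1)),
        ("c2", 2, 30.0, "synonymous", (1, 1, 1, 1, 1, 1)),
    ]
    return make_table(rows, popmap6)
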