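import numpy as np
import pytest

from mrmediate import HarmonizedSet, SummaryTable, VariantAssociation


def make_h(bx, by, sy, sx=None, snp_ids=None, exposures=None):
    """Build a HarmonizedSet from plain lists (K inferred from bx shape)."""
    bx = np.atleast_2d(np.asarray(bx, dtype=float))
    k, j = bx.shape
    if sx is None:
        sx = np.full((k, j), 0.01)
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(j)]
    if exposures is None:
        exposures = ["exposure"] if k == 1 else [f"e{i + 1}" for i in range(k)]
    return HarmonizedSet(
        snp_ids=list(snp_ids),
        exposure_names=list(exposures),
        bx=bx,
        sx=np.atleast_2d(np.asarray(sx, dtype=float)),
        by=np.asarray(by, dtype=float),
        sy=np.asarray(sy, dtype=float),
    )


def make_table(rows, trait_name="trait", trait_type="binary"):
    """rows: (snp_id, ea, oa, beta, se, pval[, eaf])"""
    records = []
    for row in rows:
        eaf = row[6] if len(row) > 6 else 0.3
        records.append(
            VariantAssociation(
                snp_id=row[0], effect_allele=row[1], other_allele=row[2],
                beta=row[3], se=row[4], pval=row[5], eaf=eaf,
            )
        )
    return SummaryTable(trait_name, trait_type, records)


@pytest.fixture
def homogeneous_h():
    """10 SNPs whose Wald ratios are all exactly 0.25."""
    rng = np.random.default_rng(3)
    bx = rng.uniform(0.05, 0.2, 10)
    sy = np.full(10, 0.02)
    return make_h(bx, 0.25 * bx, sy)
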