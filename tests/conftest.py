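import numpy as np
import pandas as pd
import pytest

from mircluster.annotation import GenomeAnnotation, MirnaRecord
from mircluster.reference import build_reference_annotation


@pytest.fixture(scope="session")
def reference_annotation() -> GenomeAnnotation:
    """The 13 published clusters' members at their printed spans plus 24
    solitary decoys placed >= 2 Mb away."""
    return build_reference_annotation(n_decoys=24, seed=0)


@pytest.fixture()
def two_group_meta() -> pd.DataFrame:
    """A balanced 2x2 diet x treatment layout with 3 samples per cell."""
    rows = []
    for diet in ("pair", "ethanol"):
        for trt in ("baseline", "LPS"):
            for i in range(3):
                rows.append(
                    {"sample_id": f"{diet}_{trt}_{i}", "diet": diet, "treatment": trt}
                )
    return pd.DataFrame(rows).set_index("sample_id")


def random_annotation(rng: np.random.Generator, n: int, chrom_span: int = 10_000_000):
    """Uniform random mature miRNAs on one chromosome (for oracle tests)."""
    starts = np.sort(rng.integers(1, chrom_span, size=n))
    return GenomeAnnotation(
        records=[
            MirnaRecord(
                name=f"m{i:03d}", chrom="chr1", start=int(s), end=int(s) + 21,
                strand="+" if rng.random() < 0.5 else "-",
            )
            for i, s in enumerate(starts)
        ]
    )


def brute_force_clusters(ann: GenomeAnnotation, window_bp: int, min_size: int):
    """Independent oracle: from the position-sorted records, repeatedly take
    the maximal run starting at the leftmost unassigned record whose span
    (max end - min start, recomputed by full scan) fits in the window."""
    out = []
    by_chrom: dict[str, list] = {}
    for r in ann.records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.name))
        i = 0
        while i < len(recs):
            j = i
            for jj in range(i, len(recs)):
                sub = recs[i : jj + 1]
                span = max(r.end for r in sub) - min(r.start for r in sub)
                if span <= window_bp:
                    j = jj
                else:
                    break
            run = recs[i : j + 1]
            if len(run) >= min_size:
                out.append([r.name for r in run])
            i = j + 1
    return out
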