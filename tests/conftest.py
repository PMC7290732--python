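import numpy as np
import pytest

from editscan.pileup_io import SiteCountTable, SiteKey


def make_table(k, n, samples=None, groups=None, genes=None):
    """SiteCountTable from plain nested lists (sites x samples)."""
    k = np.asarray(k)
    n = np.asarray(n)
    n_sites, n_samples = k.shape
    if samples is None:
        half = n_samples // 2
        samples = [f"WT{i+1}" for i in range(half)] + [
            f"KO{i+1}" for i in range(n_samples - half)
        ]
    if groups is None:
        groups = {s: ("WT" if s.startswith("WT") else "KO") for s in samples}
    sites = [
        SiteKey(
            chrom="chr1",
            pos=i + 1,
            ref_base="A",
            edited_base="G",
            strand="+",
            gene=(genes[i] if genes else f"Gene{i+1}"),
        )
        for i in range(n_sites)
    ]
    return SiteCountTable(sites=sites, samples=samples, groups=groups, k=k, n=n)


@pytest.fixture
def small_table():
    return make_table(
        k=[[1, 2, 5, 6], [0, 0, 0, 0]],
        n=[[10, 20, 15, 12], [30, 30, 30, 30]],
    )


@pytest.fixture
def site_counts_tsv(tmp_path, small_table):
    from editscan.pileup_io import write_site_counts

    path = tmp_path / "counts.tsv"
    write_site_counts(small_table, path)
    return path
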