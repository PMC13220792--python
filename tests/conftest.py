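import pytest
from hypothesis import HealthCheck, settings

import memtopo as mt

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    n_tmds=1,
    n_side=mt.INSIDE,
    tail_n=20,
    tail_c=20,
    loops=15,
    tmd_len=21,
    signal=None,
    accession="TEST1",
    tmd_aa="L",
    loop_aa="G",
):
    """Hand-built record with uniform geometry for unit tests."""
    if isinstance(loops, int):
        loops = [loops] * (n_tmds - 1)
    parts = []
    sig_len = 0
    if signal is not None:
        sig_len = signal
        parts.append("A" * sig_len)
    spans = []
    pos = sig_len
    parts.append(loop_aa * tail_n)
    pos += tail_n
    for i in range(n_tmds):
        spans.append((pos + 1, pos + tmd_len))
        parts.append(tmd_aa * tmd_len)
        pos += tmd_len
        if i < n_tmds - 1:
            parts.append(loop_aa * loops[i])
            pos += loops[i]
    parts.append(loop_aa * tail_c)
    seq = "".join(parts)
    return mt.ProteinRecord(
        accession=accession,
        gene_name="test",
        length=len(seq),
        sequence=seq,
        n_terminus_side=n_side,
        signal_peptide=(1, sig_len) if signal else None,
        tmds=[
            mt.TmdSegment(index=i + 1, start=s, end=e, sequence=seq[s - 1 : e])
            for i, (s, e) in enumerate(spans)
        ],
    )


@pytest.fixture(scope="session")
def small_config():
    return mt.default_config(n_proteins=300, seed=11)


@pytest.fixture(scope="session")
def small_proteome(small_config):
    return mt.generate_proteome(small_config)
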