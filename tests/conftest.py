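import numpy as np
import pytest

from estpoly.match import MatchedPair, hsp_from_rows

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def pair_from_rows(q_row: str, s_row: str, query_id="q", subject_id="s") -> MatchedPair:
    """MatchedPair with a single HSP built directly from gapped rows."""
    hsp = hsp_from_rows(query_id, subject_id, q_row, s_row)
    return MatchedPair(
        query_id=query_id,
        subject_id=subject_id,
        hsps=[hsp],
        matched_columns=hsp.n_columns,
        strand="+",
        query_seq=q_row.replace("-", ""),
        subject_seq=s_row.replace("-", ""),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(entries, name="in.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
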