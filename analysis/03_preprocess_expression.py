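"""Normalize the cohort expression matrix and restrict it to the signature.

The synthetic expression is already on a log-like intensity scale, so only
quantile normalization and the signature intersection apply here (probe
collapsing and batch adjustment are exercised by the test suite and are
available for real multi-cohort inputs).
"""

from _common import BULK, OUTDIR, get_config

from sig32 import io
from sig32.preprocess import intersect_signature, quantile_normalize


def main() -> None:
    cfg = get_config()
    expr = io.read_expression(BULK / "expression.tsv")
    signature = (OUTDIR / "signature.txt").read_text().split()

    normalized = quantile_normalize(expr)
    matrix, missing = intersect_signature(normalized, signature,
                                          coverage_floor=cfg.coverage_floor)
    io.write_expression(matrix, BULK / "expr_signature.tsv")
    print(f"quantile-normalized {expr.shape[1]} samples; "
          f"signature coverage {matrix.shape[0]}/{len(signature)} genes"
          + (f" (missing: {missing})" if missing else ""))


if __name__ == "__main__":
    main()
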