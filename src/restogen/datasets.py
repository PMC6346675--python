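"""Bundled published summary data for Nevada desert bighorn sheep herds.

Two small reference tables accompany the package:

* :func:`load_nevada_herds` — the published per-hunt-unit diversity summary
  (desert, historic status, number of translocation source units, mean
  expected and observed heterozygosity, and heterozygote deficiency) for the
  28 Nevada units with at least five genotyped individuals, from the
  state-wide GBS survey of 303 desert bighorn sheep at 17,095 SNPs.
* :func:`load_source_fst` — the published pairwise Hudson F_ST among the
  four remnant source herds that never received translocations: Lone
  Mountain (212), Muddy Mountains (268), River Mountains (269), and Mormon
  Mountains (271).

These are printed summary values, not genotypes; they drive the worked
examples and the desk-scale reproduction of the survey's diversity
comparisons.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .popstats import PairwiseMatrix

__all__ = ["load_nevada_herds", "load_source_fst", "SOURCE_UNITS"]

#: The four remnant source units that never received translocations.
SOURCE_UNITS = ("212", "268", "269", "271")

_NEVADA_HERDS_TSV = """\
unit	desert	n_genotyped	status	n_sources	h_e	h_o	f_is
131	GB	9	remnant	2	0.190	0.167	0.118
132	GB	6	remnant	4	0.180	0.143	0.204
161	GB	8	reintroduced	1	0.187	0.149	0.202
173	GB	5	remnant	2	0.192	0.178	0.072
181	GB	8	reintroduced	1	0.189	0.160	0.152
184	GB	6	reintroduced	1	0.184	0.152	0.176
202	GB	6	reintroduced	6	0.190	0.165	0.134
205	GB	7	reintroduced	4	0.191	0.157	0.180
211	GB	8	remnant	1	0.190	0.159	0.163
212	GB	18	remnant	0	0.178	0.157	0.122
213	GB	7	remnant	1	0.182	0.133	0.271
223	GB	8	reintroduced	1	0.186	0.165	0.112
241	GB-M	9	reintroduced	4	0.196	0.176	0.105
243	M	7	remnant	3	0.196	0.166	0.151
244	M	8	remnant	0	0.183	0.161	0.116
245	GB	6	remnant	1	0.187	0.173	0.074
253	M	16	reintroduced	2	0.186	0.147	0.210
254	M	5	reintroduced	2	0.186	0.159	0.145
261	M	5	reintroduced	1	0.187	0.170	0.094
262	M	16	remnant	0	0.186	0.142	0.234
263	M	16	remnant	2	0.192	0.161	0.162
264	M	5	remnant	1	0.185	0.141	0.238
266	M	13	remnant	0	0.196	0.152	0.223
268	M	17	remnant	0	0.182	0.132	0.273
269	M	10	remnant	0	0.191	0.154	0.195
271	M	10	remnant	0	0.177	0.154	0.131
272	M	6	reintroduced	3	0.192	0.184	0.044
NTTR	GB-M	19	reintroduced	2	0.201	0.190	0.054
"""

_SOURCE_FST = {
    ("212", "268"): 0.082,
    ("212", "269"): 0.075,
    ("212", "271"): 0.076,
    ("268", "269"): 0.067,
    ("268", "271"): 0.064,
    ("269", "271"): 0.063,
}


def load_nevada_herds() -> pd.DataFrame:
    """Published diversity summary of the 28 qualifying Nevada hunt units.

    Columns: ``unit, desert, n_genotyped, status, n_sources, h_e, h_o, f_is``.
    """
    return pd.read_csv(io.StringIO(_NEVADA_HERDS_TSV), sep="\t", dtype={"unit": str})


def load_source_fst() -> PairwiseMatrix:
    """Published pairwise Hudson F_ST among the four remnant source herds."""
    units = list(SOURCE_UNITS)
    vals = np.zeros((4, 4))
    for (a, b), v in _SOURCE_FST.items():
        i, j = units.index(a), units.index(b)
        vals[i, j] = vals[j, i] = v
    return PairwiseMatrix(units, vals, kind="fst")
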