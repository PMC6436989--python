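"""JTT amino-acid substitution model constants.

Exchangeabilities and stationary frequencies of the Jones-Taylor-Thornton
(1992) model, in the standard PAML ``jones.dat`` layout: the lower triangle
is stored column-wise in the PAML residue order A R N D C Q E G H I L K M F
P S T W Y V.  Values are the published accepted-point-mutation counts; only
ratios matter, as the generator built from them is rescaled to one expected
substitution per site per unit time.
"""

from __future__ import annotations

import numpy as np

#: PAML residue order used by the tables below
PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"

_JTT_LOWER_COLWISE = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9, 11, 298,
    45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64, 126, 20, 17,
    528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232, 8, 70, 16, 10, 49,
    767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46, 31, 9, 5, 59, 69, 17, 23, 7,
    31, 78, 14, 223, 42, 115, 209, 62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51,
    18, 24, 20, 119, 26, 12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14,
    5, 24, 201, 33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21,
    479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4,
    21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

_JTT_FREQS = [
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830, 0.073152,
    0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126, 0.050901, 0.068765,
    0.058565, 0.014261, 0.032102, 0.066005,
]


def jtt_exchangeabilities_and_frequencies(alphabet: str) -> tuple[np.ndarray, np.ndarray]:
    """The symmetric 20x20 JTT exchangeability matrix and stationary
    frequencies, reordered from PAML order to the given alphabet."""
    s = np.zeros((20, 20))
    it = iter(_JTT_LOWER_COLWISE)
    for j in range(20):  # column-wise lower triangle
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = next(it)
    pi = np.asarray(_JTT_FREQS, dtype=float)
    pi = pi / pi.sum()
    perm = [PAML_ORDER.index(a) for a in alphabet]
    return s[np.ix_(perm, perm)], pi[perm]
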