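"""Import shim for the synthetic-accessibility (SA) scorer.

RDKit ships the standard fragment-contribution SA implementation in its
Contrib tree, which is not an importable package; this module puts it on
``sys.path`` once and re-exports the scoring function.
"""

from __future__ import annotations

import os
import sys

from rdkit.Chem import RDConfig

_SA_DIR = os.path.join(RDConfig.RDContribDir, "SA_Score")
if _SA_DIR not in sys.path:
    sys.path.append(_SA_DIR)

import sascorer  # noqa: E402

calculate_sa_score = sascorer.calculateScore

__all__ = ["calculate_sa_score"]
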