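"""CSV readers/writers for panel response and rating matrices.

Dialect: comma-separated UTF-8, header row required, "." decimal mark. Rows
are panelists, columns are item or scenario identifiers; the first column
holds the panelist id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError


def read_panel_responses(path: str | Path) -> pd.DataFrame:
    """Read and validate a panelists x items Likert matrix.

    Every cell must be an integer in 1..5; violations are reported with their
    panelist row and item column.
    """
    frame = pd.read_csv(path, index_col=0)
    if frame.empty:
        raise InvalidInputError(f"{path}: empty response matrix")
    for col in frame.columns:
        values = frame[col]
        if values.isna().any():
            row = values.index[values.isna()][0]
            raise InvalidInputError(f"{path}: missing response at row {row!r}, column {col!r}")
        arr = values.to_numpy()
        ok = np.isfinite(arr) & (arr == np.round(arr)) & (arr >= 1) & (arr <= 5)
        if not ok.all():
            row = values.index[~ok][0]
            raise InvalidInputError(
                f"{path}: response at row {row!r}, column {col!r} is not an integer in 1..5 "
                f"(got {values[row]!r})"
            )
    return frame.astype(int)


def write_panel_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=True)


#: Ratings matrices share the response-matrix format.
read_ratings = read_panel_responses
write_ratings = write_panel_responses
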