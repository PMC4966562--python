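"""Minimal TOML emission for phantom and protocol files.

Reading goes through :mod:`tomllib`; the standard library has no writer, so
this emits the small subset needed here: nested tables, arrays of tables,
and scalar/list values.
"""

from __future__ import annotations


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        escaped = v.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def dumps(data: dict, _prefix: str = "") -> str:
    """Serialize a nested dict to TOML text.

    Dicts become tables, lists of dicts become arrays of tables, everything
    else is emitted inline.
    """
    lines: list[str] = []
    scalars = {
        k: v
        for k, v in data.items()
        if not isinstance(v, dict)
        and not (isinstance(v, list) and v and isinstance(v[0], dict))
    }
    for k, v in scalars.items():
        lines.append(f"{k} = {_fmt_value(v)}")
    for k, v in data.items():
        if k in scalars:
            continue
        full = f"{_prefix}{k}"
        if isinstance(v, dict):
            lines.append(f"\n[{full}]")
            lines.append(dumps(v, _prefix=full + "."))
        else:  # list of dicts -> array of tables
            for item in v:
                lines.append(f"\n[[{full}]]")
                lines.append(dumps(item, _prefix=full + "."))
    return "\n".join(lines).strip() + "\n"
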