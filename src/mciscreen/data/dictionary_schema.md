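# Dictionary file format

Flat, line-oriented, UTF-8, tab-separated. Lines starting with `#` are
comments; `#version: <label>` sets the dictionary version. Every other
non-blank line is one concept record with exactly five fields:

| field       | meaning                                                        |
|-------------|----------------------------------------------------------------|
| cui         | short uppercase concept identifier, unique within the file     |
| role        | `feature`, `patient_exclusion`, `mention_exclusion`, `negation_guard` |
| max_gap     | non-negative integer: intervening word tokens allowed between consecutive phrase words (ignored for single-word patterns) |
| description | free text (no tabs)                                            |
| patterns    | `\|`-separated list of patterns; phrase words separated by single spaces; may be empty |

Example:

```
#mciscreen-dictionary
#version: site-custom-1.0
#fields: cui	role	max_gap	description	patterns
WANDER	feature	2	Wandering or getting lost	wander|getting lost
```

Loading is strict: duplicate CUIs, unknown roles and empty files are hard
errors. Single-word patterns are expanded with rule-generated -s/-ed/-ing
inflections at pattern-compilation time; multi-word phrases are matched as
written, case-insensitively.
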