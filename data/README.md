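# Real-network datasets (not bundled)

The real-network spot checks (`tests/test_acceptance.py::test_c2_*` and
`scripts/acceptance.py` targets t1–t4) consume edge lists of four published
networks:

| name        | N    | M    | expected n_D |
|-------------|------|------|--------------|
| TRN-EC-2    | 423  | 578  | 0.728        |
| TRN-Yeast-2 | 688  | 1079 | 0.821        |
| Grassland   | 88   | 137  | 0.522        |
| USair97     | 332  | 2126 | 0.334        |

These are third-party datasets distributed as a supplementary ZIP alongside
the source publication (PLOS ONE, doi:10.1371/journal.pone.0325824, S1 File)
and are **not redistributed here**. To enable the checks, download the ZIP,
extract it, and place each network as a plain-text edge list (one
`source target` pair per line, whitespace- or tab-delimited, `#` comments
allowed) anywhere under this `data/` directory with the dataset name in the
file name, e.g.

```
data/real/TRN-EC-2.tsv
data/real/TRN-Yeast-2.tsv
data/real/Grassland.tsv
data/real/USair97.tsv
```

Matching is case-insensitive and ignores `-`/`_`. Without these files the
t1–t4 targets are omitted from the acceptance report and the corresponding
tests fail with an explanatory message.
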