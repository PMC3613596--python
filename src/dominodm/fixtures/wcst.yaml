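# Wisconsin Card Sorting Test scenario configuration.
#
# Target cards, the criterion cycle, the default switch threshold, and
# the worked single-trial example (the diamond shape is admitted solely
# for that example).  Cards are [number, shape, color].
format_version: 1

criteria: [color, form, number]
switch_after: 6

targets:
  - [1, triangle, red]
  - [2, star, green]
  - [3, cross, yellow]
  - [4, circle, blue]

worked_example:
  card: [1, diamond, green]
  targets:
    - [1, diamond, red]
    - [2, star, green]
    - [3, cross, blue]
    - [4, circle, yellow]
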