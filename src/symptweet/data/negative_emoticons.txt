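# Negative emojis and emoticons: faces associated with illness, sadness,
# anger or exhaustion. One token per line; '#' lines are comments.
# Synthetic curation: the original study's list was unpublished, so this is an
# editable stand-in covering the examples it names (the crying emoticon :'(,
# the medical-mask face) plus the common sad/ill/tired faces.
😷
🤒
🤕
🤧
🤢
🤮
😢
😭
😞
😔
😟
😕
🙁
☹
☹️
😖
😣
😫
😩
😪
😴
😤
😠
😡
💀
😿
:(
:-(
:'(
:'-(
;(
;-(
=(
D:
:[
:-[
:c
:'‑(
(T_T)
(;_;)
(ToT)
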