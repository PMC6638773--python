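# Laughter / positivity tokens: internet slang, laughing emojis and smiling
# emoticons. One token per line; lines starting with '#' are comments.
# Synthetic curation: the original study's list was unpublished, so this is an
# editable stand-in covering the examples it names (lol, lmao) plus the common
# laughing faces.
lol
lmao
rofl
roflmao
lolol
ha
haha
hahaha
hahah
hehe
heh
😂
🤣
😹
😆
😄
😃
😁
😀
😊
😸
:)
:-)
:D
:-D
=D
;)
;-)
:p
:-p
xD
XD
^_^
(^_^)
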