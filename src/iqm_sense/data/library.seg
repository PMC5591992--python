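IQMSEG 1
segment segment1_3x3
leaf_width_cm 0.5
first_pair_offset_cm -1.5
pair 0 -1.5 1.5
pair 1 -1.5 1.5
pair 2 -1.5 1.5
pair 3 -1.5 1.5
pair 4 -1.5 1.5
pair 5 -1.5 1.5
segment segment2_irregular
leaf_width_cm 0.5
first_pair_offset_cm -2.5
pair 0 -2.9728853799854704 3.1556869321610117
pair 1 -3.6266623751124256 3.481056791851271
pair 2 -2.8568073581931137 2.6124438325436468
pair 3 -2.1202189052355584 2.1142321417967884
pair 4 -1.4625523383978232 1.893402829322024
pair 5 -1.6846948286408487 1.9206165664971024
pair 6 -1.9264068456522412 1.8038823736252896
pair 7 -2.686434547584346 2.32793156183767
pair 8 -3.308862650456741 2.823793121286593
pair 9 -3.700657180398559 3.1807714394214672
segment segment3_irregular
leaf_width_cm 0.5
first_pair_offset_cm -4.0
pair 0 -3.995509635197943 3.856532856283575
pair 1 -3.5253741812442163 3.308387924867236
pair 2 -2.7186676040918525 2.961069574888207
pair 3 -2.6473824741374226 3.0439494983290696
pair 4 -2.390106794635016 3.0479552652115203
pair 5 -3.537839807942004 4.008178898171473
pair 6 -3.82459116182475 4.152467112073861
pair 7 -5.055581009680944 5.215057925899632
pair 8 -5.419237550619363 5.293164523419127
pair 9 -5.631311062821185 5.246906173969503
pair 10 -6.500950737436385 5.711463527195235
pair 11 -6.190731371724268 5.453474194354867
pair 12 -6.278115294427628 5.372345732376584
pair 13 -5.491723882962393 5.110633093041713
pair 14 -4.666595113105085 4.714621692018486
pair 15 -3.4227775940788585 3.847296731970571
segment segment4_irregular
leaf_width_cm 0.5
first_pair_offset_cm -3.25
pair 0 -4.666101047542253 4.990249155243693
pair 1 -4.169733812619176 4.476402870543913
pair 2 -3.135405686233313 3.393073050247392
pair 3 -3.077783710106577 2.7744667598653767
pair 4 -2.4783048810167276 2.20175015368393
pair 5 -2.429866364029456 1.881263822448095
pair 6 -2.2820417568905182 2.304421076397189
pair 7 -3.120511260531828 2.8016592355921666
pair 8 -4.011764813490319 4.096932450237326
pair 9 -4.4633049557352695 4.089149418717126
pair 10 -4.7863655341319715 4.809312917704758
pair 11 -4.874809774036218 4.8116373954049125
pair 12 -4.399480384359078 4.454207713191423
segment segment5_1x1
leaf_width_cm 0.5
first_pair_offset_cm -0.5
pair 0 -0.5 0.5
pair 1 -0.5 0.5
segment segment6_irregular
leaf_width_cm 0.5
first_pair_offset_cm -2.25
pair 0 -2.3359435483528483 1.9939346036519816
pair 1 -3.128251650821484 2.64932741810918
pair 2 -3.12563307758799 2.9293436117295615
pair 3 -2.691326327855405 2.7037034403306732
pair 4 -2.006882138798126 2.0384897549470526
pair 5 -1.6039023061993443 1.5435740642280589
pair 6 -1.2488337216902026 1.5504575210581617
pair 7 -1.61117915603685 1.6816396618048475
pair 8 -2.6468446441226736 2.490733352675552
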