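species	n	matK	rbcL	nrITS2	combined	gap	conflated	conflated_truncated
Ac. sahniana	3	+	+	+	+	1		0
Af. dawei	1	-	-	-	-	0	Af. gracilior;Af. mannii;Af. falcatus	1
Af. falcatus	2	-	-	-	-	0	Af. gracilior;Af. mannii;Af. usambarensis	1
Af. gracilior	2	-	-	+	+	0	Af. falcatus;Af. usambarensis;Af. dawei	1
Af. mannii	2	-	-	-	+	0	Af. falcatus;Af. usambarensis;Af. dawei	1
Af. usambarensis	1	-	-	-	-	0	Af. gracilior;Af. mannii;Af. falcatus	1
Dc. compactus	1	-	-	-	-	0	Dc. kinabaluensis;Dc. imbricatus;Dc. expansus	0
Dc. dacrydioides	2	+	+	+	+	1		0
Dc. expansus	1	-	-	-	-	0	Dc. kinabaluensis;Dc. imbricatus;Dc. compactus	0
Dc. imbricatus	3	-	-	+	+	0	Dc. expansus;Dc. compactus;Dc. kinabaluensis	0
Dc. kinabaluensis	2	-	-	-	+	0	Dc. expansus;Dc. compactus;Dc. imbricatus	0
Dd. balansae	1	-	-	-	-	0	Dd. araucarioides;Dd. cupressinum;Dd. nausoriense	1
Dd. beccarii	1	-	+	+	+	1	Dd. gracile;Dd. xanthandrum	0
Dd. cupressinum	2	+	-	+	+	1	Dd. guillauminii;Dd. araucarioides;Dd. balansae	1
Dd. elatum	1	+	+	+	+	1		0
Dd. guillauminii	3	-	-	-	-	0	Dd. araucarioides;Dd. cupressinum;Dd. nausoriense	1
Dd. ×suprinii	1	-	-	-	-	0	Dd. araucarioides;Dd. cupressinum;Dd. nausoriense	1
F. papuanum	1	+	+	+	+	1		0
F. taxioides	1	+	+	+	+	1		0
La. franklinii	2	+	+	+	+	1		0
Le. intermedius	1	+	+	+	+	1		0
Ma. colensoi	1	+	-	+	+	1	Le. intermedius	0
Mi. tetragona	2	+	+	+	+	1		0
N. fleuryi	1	+	+	+	+	1		0
N. formosensis	1	-	-	-	-	0	N. motleyi;N. nagi	0
N. nagi	2	-	-	-	-	0	N. motleyi;N. formosensis	0
N. wallichiana	3	+	-	+	+	1	N. motleyi	0
Ph. fitzgeraldii	2	+	+	+	+	1		0
Po. acutifolius	2	-	-	-	-	0	Po. cunninghamii;Po. totara;Po. hallii	0
Po. affinis	1	-	+	+	+	1	Po. degeneri;Po. rubens;Po. insularis	1
Po. alpinus	2	-	-	-	-	0	Po. lawrencei;Po. gnidioides;Po. nivalis	1
Po. angustifolius	1	-	-	-	-	0	Po. salignus	0
Po. archboldii	1	+	-	-	+	1	Po. drouynianus;Po. polystachyus;Po. thailandensis	1
Po. assamica	1	-	-	-	-	0	Po. drouynianus;Po. deflexus;Po. insularis	1
Po. bracteatus	1	-	-	-	+	1	Po. neriifolius;Po. pseudobracteatus	0
Po. brassii	2	-	-	-	+	1	Po. drouynianus;Po. thailandensis;Po. deflexus	1
Po. celatus	1	-	-	-	+	1	Po. guatemalensis;Po. coriaceus;Po. sellowii	1
Po. chinensis	1	-	-	-	-	0	Po. nakaii;Po. pilgeri;Po. annamiensis	1
Po. chingianus	1	-	-	-	-	0	Po. nakaii;Po. pilgeri;Po. annamiensis	1
Po. coriaceus	2	-	-	-	-	0	Po. guatemalensis;Po. trinitensis;Po. celatus	1
Po. costalis	1	-	-	-	-	0	Po. nakaii;Po. pilgeri;Po. annamiensis	1
Po. cunninghamii	1	-	-	-	-	0	Po. totara;Po. acutifolius;Po. hallii	0
Po. degeneri	1	-	-	-	-	0	Po. affinis;Po. insularis;Po. ledermannii	1
Po. dispermus	1	+	+	+	+	1		0
Po. drouynianus	1	-	+	-	+	1	Po. polystachyus;Po. thailandensis;Po. insularis	1
Po. elatus	2	+	+	+	+	1		0
Po. elongatus	1	+	+	-	+	1	Po. polystachyus;Po. milanjianus;Po. henkelii	1
Po. fasciculus	1	-	-	-	-	0	Po. nakaii;Po. pilgeri;Po. annamiensis	1
Po. forrestii	1	-	-	-	-	0	Po. nakaii;Po. pilgeri;Po. annamiensis	1
Po. gnidioides	1	+	-	+	+	1	Po. alpinus;Po. lawrencii	0
Po. grayae	1	+	-	+	+	1	Po. lucienii;Po. rumphii;Po. sylvestris	1
Po. guatemalensis	3	-	-	-	-	0	Po. tepuiensis;Po. brasiliensis;Po. coriaceus	1
Po. hallii	2	-	-	-	-	0	Po. totara;Po. acutifolius;Po. cunninghamii	0
Po. henkelii	3	-	-	-	-	0	Po. polystachyus;Po. elongatus;Po. milanjianus	1
Po. lambertii	3	+	+	+	+	1		0
Po. latifolius	2	-	-	-	-	0	Po. polystachyus;Po. elongatus;Po. milanjianus	1
Po. lawrencii	2	-	-	-	-	0	Po. lawrencei;Po. gnidioides;Po. nivalis	1
Po. ledermannii	1	-	-	-	-	0	Po. polystachyus;Po. thailandensis;Po. decipiens	1
Po. longifoliolatus	2	-	-	-	+	1	Po. rumphii;Po. grayae;Po. lucienii	1
Po. lucienii	2	-	-	-	-	0	Po. rumphii;Po. grayae;Po. decumbens	1
Po. macrophyllus	3	-	-	-	-	0	Po. nakaii;Po. pilgeri;Po. annamiensis	1
Po. madagascariensis	1	+	+	+	+	1		0
Po. matudae	2	-	-	-	-	0	Po. oleifolius;Po. guatemalensis	0
Po. milanjianus	1	-	-	-	-	0	Po. polystachyus;Po. elongatus;Po. henkelii	1
Po. neriifolius	2	-	-	-	-	0	Po. drouynianus;Po. insularis;Po. ledermannii	1
Po. nivalis	2	-	+	-	+	1	Po. lawrencei;Po. totara;Po. acutifolius	1
Po. novae-caledoniae	3	-	-	-	+	1	Po. sylvestris;Po. beecherae	0
Po. nubigenus	1	-	+	+	+	1	Po. atjehensis	0
Po. oleifolius	2	-	-	-	-	0	Po. trinitensis;Po. salicifolius;Po. rusbyi	1
Po. pallidus	1	-	-	-	-	0	Po. affinis;Po. insularis;Po. ledermannii	1
Po. parlatorei	2	-	-	+	+	1	Po. transiens;Po. sprucei	0
Po. pilgeri	2	-	+	-	+	1	Po. nakaii;Po. costalis;Po. fasciculus	1
Po. polystachyus	2	-	-	-	+	0	Po. drouynianus;Po. deflexus;Po. insularis	1
Po. purdieanus	1	+	+	+	+	1		0
Po. ramosii	1	-	-	-	+	1	Po. thailandensis;Po. insularis;Po. assamica	1
Po. rubens	2	-	-	-	-	0	Po. drouynianus;Po. polystachyus;Po. thailandensis	1
Po. rumphii	2	-	-	+	+	1	Po. lucienii;Po. sylvestris;Po. grayae	1
Po. salignus	3	-	-	-	-	0	Po. angustifolius	0
Po. sellowii	3	+	-	-	+	1	Po. tepuiensis;Po. celatus;Po. oleifolius	1
Po. smithii	1	+	+	+	+	1		0
Po. spinolosus	3	-	-	+	+	1	Po. dispermus;Po. drouynianus;Po. rostratus	1
Po. sprucei	1	-	-	-	+	1	Po. glomeratus;Po. lambertii;Po. transiens	1
Po. subtropicalis	1	-	-	-	-	0	Po. drouynianus;Po. deflexus;Po. insularis	1
Po. sylvestris	3	-	-	-	-	0	Po. rumphii;Po. grayae;Po. beecherae	1
Po. thailandensis	1	-	-	-	-	0	Po. drouynianus;Po. insularis;Po. ledermannii	1
Po. totara	3	-	-	-	-	0	Po. cunninghamii;Po. acutifolius;Po. hallii	0
Po. urbanii	1	+	-	+	+	1	Po. guatemalensis;Po. celatus;Po. oleifolius	1
Pr. amara	2	+	+	+	+	1		0
Pr. andina	1	+	-	+	+	1	Pr. exigua;Pr. montana	0
Pr. ferruginea	1	-	-	-	-	0	Pr. ferruginoides	0
Pr. ferruginoides	1	-	-	+	+	0	Pr. ferruginea	0
Pr. ladei	2	+	+	+	+	1		0
Pr. taxifolia	2	+	+	+	+	1		0
R. comptonii	1	+	-	-	+	1	R. minus;R. rospigliosii;R. vitiense	0
R. minus	1	-	-	+	+	1	R. comptonii	0
R. rospigliosii	2	+	+	-	+	1	R. comptonii;R. vitiense	0
S. conspicua	2	+	+	+	+	1		0
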