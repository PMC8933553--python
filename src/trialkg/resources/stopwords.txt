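# English stop words removed before lemmatization of adverse-event terms
# and before TF-IDF weighting of outcome titles. One token per line.
a
an
the
and
or
but
nor
not
no
of
in
on
at
to
for
from
by
with
without
as
is
are
was
were
be
been
being
am
do
does
did
have
has
had
this
that
these
those
it
its
their
his
her
than
then
so
if
while
about
against
between
into
through
during
before
after
above
below
up
down
out
off
over
under
again
further
once
here
there
when
where
why
how
all
any
both
each
few
more
most
other
some
such
only
own
same
too
very
can
will
per
via
due
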